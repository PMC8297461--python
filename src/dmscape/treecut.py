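"""Hybrid dynamic tree cutting for dendrogram cluster detection.

Implements the Dynamic Hybrid algorithm of Langfelder, Zhang & Horvath
(2008): branches of a hierarchical-clustering dendrogram become preliminary
clusters when they satisfy minimum-size, core-scatter and gap criteria
(parameterized by ``deep_split``), and a subsequent assignment stage attaches
each remaining unlabelled object to the nearest cluster whenever its average
dissimilarity to that cluster is within the cluster's own assignment radius.
Objects that stay unlabelled are reported with id 0 (outliers).

Two deterministic choices close gaps the published description leaves open
(see the package methods note): the core of a branch is defined as the
``core_size`` members with the *lowest* joining heights (rather than an
append-order prefix, which depends on input ordering), and when two branches
merge without splitting, absorbed members keep their original joining
heights. Both choices make the cut invariant to input row order up to
relabelling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["cutree_hybrid", "DEEP_SPLIT_PARAMS"]

#: deep_split level -> (max_core_scatter, min_gap), as fractions of the
#: dendrogram height range between the 5th-percentile merge and the cut height.
DEEP_SPLIT_PARAMS = {
    0: (0.64, 0.27),
    1: (0.73, 0.2025),
    2: (0.82, 0.135),
    3: (0.91, 0.0675),
    4: (0.95, 0.0375),
}


@dataclass
class _Branch:
    members: list[int] = field(default_factory=list)
    heights: list[float] = field(default_factory=list)
    basic: bool = True
    sub_clusters: list[list[int]] = field(default_factory=list)
    unassigned: list[int] = field(default_factory=list)


def _core_size(branch_size: int, min_cluster_size: int) -> int:
    base = min_cluster_size // 2 + 1
    if base < branch_size:
        return int(base + math.sqrt(branch_size - base))
    return branch_size


def _core_scatter(branch: _Branch, min_cluster_size: int) -> float:
    k = _core_size(len(branch.members), min_cluster_size)
    core = np.partition(np.asarray(branch.heights, dtype=float), k - 1)[:k]
    return float(core.mean())


def _passes(
    branch: _Branch,
    merge_height: float,
    min_cluster_size: int,
    max_abs_core_scatter: float,
    min_abs_gap: float,
) -> bool:
    if len(branch.members) < min_cluster_size:
        return False
    scatter = _core_scatter(branch, min_cluster_size)
    if scatter >= max_abs_core_scatter:
        return False
    return (merge_height - scatter) > min_abs_gap


def _validate_dist(dist: np.ndarray) -> np.ndarray:
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(dist, dist.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    return dist


def cutree_hybrid(
    linkage_matrix: np.ndarray,
    dist: np.ndarray,
    deep_split: int = 0,
    min_cluster_size: int = 20,
    cut_height: float | None = None,
    pam_stage: bool = True,
) -> np.ndarray:
    """Assign objects of a dendrogram to clusters via the Dynamic Hybrid cut.

    Parameters
    ----------
    linkage_matrix:
        SciPy linkage array built from ``dist`` (monotone heights, e.g.
        average linkage).
    dist:
        Full square dissimilarity matrix the dendrogram was built from.
    deep_split:
        Split sensitivity 0-4; higher values split more aggressively by
        relaxing the core-scatter bound and shrinking the required gap.
    min_cluster_size:
        Minimum number of objects for a branch to become a cluster.
    cut_height:
        Merges above this height never join branches; defaults to 99% of the
        tallest merge.
    pam_stage:
        Whether to run the assignment stage attaching unlabelled objects to
        the nearest cluster within its assignment radius.

    Returns
    -------
    numpy.ndarray of int
        One label per object; ids >= 1 are clusters numbered by decreasing
        size (ties by smallest member index), 0 marks unassigned objects.
    """
    dist = _validate_dist(dist)
    n = dist.shape[0]
    if n < 2:
        return np.zeros(n, dtype=int)
    Z = np.asarray(linkage_matrix, dtype=float)
    if Z.shape[0] != n - 1:
        raise ValueError("linkage does not match distance matrix size")
    if deep_split not in DEEP_SPLIT_PARAMS:
        raise ValueError(f"deep_split must be in {sorted(DEEP_SPLIT_PARAMS)}")

    heights = Z[:, 2]
    n_merge = n - 1
    if cut_height is None:
        cut_height = 0.99 * float(heights.max())
    sorted_h = np.sort(heights)
    ref_idx = max(int(round(0.05 * n_merge)) - 1, 0)
    ref_height = float(sorted_h[ref_idx])
    frac_scatter, frac_gap = DEEP_SPLIT_PARAMS[deep_split]
    span = cut_height - ref_height
    max_abs_core_scatter = ref_height + frac_scatter * span
    min_abs_gap = frac_gap * span

    branch_of: dict[int, _Branch] = {}
    consumed: set[int] = set()

    def passes(b: _Branch, h: float) -> bool:
        return _passes(b, h, min_cluster_size, max_abs_core_scatter, min_abs_gap)

    for i in range(n_merge):
        h = float(heights[i])
        if h > cut_height:
            break
        a, b = int(Z[i, 0]), int(Z[i, 1])
        node_id = n + i
        ba = branch_of.get(a) if a >= n else None
        bb = branch_of.get(b) if b >= n else None
        consumed.add(a)
        consumed.add(b)

        if a < n and b < n:
            branch_of[node_id] = _Branch(members=[a, b], heights=[h, h])
            continue
        if (a < n) != (b < n):
            singleton = a if a < n else b
            br = ba if ba is not None else bb
            assert br is not None
            if br.basic:
                br.members.append(singleton)
                br.heights.append(h)
            else:
                br.members.append(singleton)
                br.unassigned.append(singleton)
            branch_of[node_id] = br
            continue

        assert ba is not None and bb is not None
        if ba.basic and bb.basic:
            if passes(ba, h) and passes(bb, h):
                merged = _Branch(
                    members=ba.members + bb.members,
                    heights=ba.heights + bb.heights,
                    basic=False,
                    sub_clusters=[list(ba.members), list(bb.members)],
                )
            else:
                big, small = (ba, bb) if len(ba.members) >= len(bb.members) else (bb, ba)
                merged = _Branch(
                    members=big.members + small.members,
                    heights=big.heights + small.heights,
                )
        elif ba.basic != bb.basic:
            comp, basic = (ba, bb) if not ba.basic else (bb, ba)
            if passes(basic, h):
                comp.sub_clusters.append(list(basic.members))
            else:
                comp.unassigned.extend(basic.members)
            comp.members = comp.members + basic.members
            comp.heights = comp.heights + basic.heights
            merged = comp
        else:
            merged = _Branch(
                members=ba.members + bb.members,
                heights=ba.heights + bb.heights,
                basic=False,
                sub_clusters=ba.sub_clusters + bb.sub_clusters,
                unassigned=ba.unassigned + bb.unassigned,
            )
        branch_of[node_id] = merged

    # roots: processed nodes never consumed, plus never-merged singletons
    clusters: list[list[int]] = []
    unassigned: list[int] = []
    seen: set[int] = set()
    root_nodes = [nid for nid in branch_of if nid not in consumed]
    for nid in root_nodes:
        br = branch_of[nid]
        if id(br) in seen:
            continue
        seen.add(id(br))
        if br.basic:
            if passes(br, cut_height):
                clusters.append(br.members)
            else:
                unassigned.extend(br.members)
        else:
            clusters.extend(br.sub_clusters)
            unassigned.extend(br.unassigned)
    in_branch = {m for nid in branch_of if nid not in consumed for m in branch_of[nid].members}
    unassigned.extend(i for i in range(n) if i not in in_branch)

    labels = np.zeros(n, dtype=int)
    for cid, members in enumerate(clusters, start=1):
        labels[members] = cid

    if pam_stage and clusters and unassigned:
        # assignment radius: the cluster diameter (largest within-cluster
        # dissimilarity) — a point whose average dissimilarity to the cluster
        # is within the diameter plausibly belongs to it
        radii = np.array(
            [float(dist[np.ix_(m, m)].max()) if len(m) > 1 else 0.0 for m in clusters]
        )
        for j in sorted(unassigned):
            dbar = np.array([dist[j, members].mean() for members in clusters])
            k = int(np.argmin(dbar))
            if dbar[k] <= radii[k]:
                labels[j] = k + 1

    return _renumber_by_size(labels)


def _renumber_by_size(labels: np.ndarray) -> np.ndarray:
    """Renumber cluster ids 1..k by decreasing size; ties by smallest member index."""
    out = np.zeros_like(labels)
    ids = [c for c in np.unique(labels) if c != 0]
    order = sorted(
        ids,
        key=lambda c: (-int((labels == c).sum()), int(np.flatnonzero(labels == c)[0])),
    )
    for new, old in enumerate(order, start=1):
        out[labels == old] = new
    return out
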