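"""Amino acid subtypes: cluster positions of each amino acid by profile shape.

The three-step procedure, applied independently to positions of each
wild-type amino acid:

1. split off *permissive* positions — every substitution has |ER| below a
   threshold (default 0.4), so the profile's direction is mostly noise;
2. hierarchically cluster the remaining positions with average linkage and
   cosine distance on their PC2-PC20 scores (PCA fit across the whole
   landscape; PC1 is excluded because it tracks mean ER, which would
   otherwise dominate);
3. cut the dendrogram with the hybrid dynamic tree cut.

Labels are ``XP`` (permissive), ``XO`` (outlier) and ``X1, X2, ...`` for the
main subtypes of amino acid X, numbered from most to least frequent.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .constants import AA_ORDER
from .ingest import ProfileSet
from .landscape import PC_COLUMNS, fit_pca
from .treecut import cutree_hybrid

LABEL_RE = re.compile(r"^[A-Y][PO]$|^[A-Y][1-9][0-9]*$")


@dataclass
class ClusteringParams:
    """Knobs of the subtype clustering.

    ``deep_split`` maps amino acids to split sensitivity (0 or 1; anything
    the tree cut supports); unlisted amino acids use ``default_deep_split``.
    """

    permissive_threshold: float = 0.4
    pc_range: tuple[int, int] = (2, 20)
    min_cluster_size: int = 20
    deep_split: dict[str, int] = field(default_factory=dict)
    default_deep_split: int = 0

    def __post_init__(self) -> None:
        if self.permissive_threshold <= 0:
            raise ValueError("permissive_threshold must be positive")
        lo, hi = self.pc_range
        if not (1 <= lo <= hi <= 20):
            raise ValueError("pc_range must satisfy 1 <= lo <= hi <= 20")

    def deep_split_for(self, aa: str) -> int:
        return self.deep_split.get(aa, self.default_deep_split)

    def pc_columns(self) -> list[str]:
        lo, hi = self.pc_range
        return [f"PC{i}" for i in range(lo, hi + 1)]


def split_permissive(
    profiles: ProfileSet, threshold: float = 0.4
) -> tuple[pd.Index, pd.Index]:
    """Partition positions into (permissive, clusterable).

    A position is permissive iff every one of its 20 ER entries has
    magnitude strictly below the threshold.
    """
    max_abs = profiles.er.abs().max(axis=1)
    mask = max_abs < threshold
    return profiles.index[mask], profiles.index[~mask]


def cosine_distance(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine distance ``1 - u.v / (|u||v|)`` in [0, 2].

    Measures only the angle between two profiles, ignoring magnitude — the
    reason permissive (near-zero) positions must be removed first.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine distance is undefined for a zero vector")
    return float(1.0 - (u @ v) / (nu * nv))


def _cosine_matrix(X: np.ndarray) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        D = squareform(pdist(X, metric="cosine"))
    # exact-zero rows (profiles identical to the landscape mean along these
    # PCs) have undefined direction; treat them as uninformative (distance 1)
    return np.nan_to_num(D, nan=1.0)


def cluster_amino_acid(
    pcs: np.ndarray, params: ClusteringParams, deep_split: int | None = None
) -> np.ndarray:
    """Cluster the PC2-PC20 vectors of one amino acid's clusterable positions.

    Returns one id per row: ids >= 1 are subtypes, 0 marks outliers.
    """
    pcs = np.asarray(pcs, dtype=float)
    n = len(pcs)
    if n < 2:
        if n:
            warnings.warn("fewer than 2 clusterable positions; all marked outliers", stacklevel=2)
        return np.zeros(n, dtype=int)
    ds = params.default_deep_split if deep_split is None else deep_split
    D = _cosine_matrix(pcs)
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    return cutree_hybrid(Z, D, deep_split=ds, min_cluster_size=params.min_cluster_size)


def label_subtypes(
    wt_aa: str,
    cluster_ids: np.ndarray,
    pcs: np.ndarray | None = None,
) -> list[str]:
    """Turn cluster ids of one amino acid into subtype labels.

    Clusters are renumbered 1..k by decreasing size; equal sizes are broken
    by smaller mean intra-cluster cosine distance (when ``pcs`` are given),
    then by lowest member index, so labelling is deterministic. Id 0 becomes
    the outlier label ``XO``.
    """
    cluster_ids = np.asarray(cluster_ids)
    ids = [c for c in np.unique(cluster_ids) if c != 0]

    def tightness(c: int) -> float:
        if pcs is None:
            return 0.0
        members = np.flatnonzero(cluster_ids == c)
        if len(members) < 2:
            return 0.0
        D = _cosine_matrix(pcs[members])
        return float(D[np.triu_indices(len(members), 1)].mean())

    order = sorted(
        ids,
        key=lambda c: (
            -int((cluster_ids == c).sum()),
            tightness(c),
            int(np.flatnonzero(cluster_ids == c)[0]),
        ),
    )
    rank = {c: i + 1 for i, c in enumerate(order)}
    return [f"{wt_aa}O" if c == 0 else f"{wt_aa}{rank[c]}" for c in cluster_ids]


def assign_subtypes(
    profiles: ProfileSet,
    params: ClusteringParams | None = None,
    pc_scores: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Run the full subtype pipeline over a landscape.

    The PCA basis is fit on the whole landscape (permissive positions
    included); only the clustering itself excludes them. Returns a frame with
    the position key columns and a ``label`` column.
    """
    params = params or ClusteringParams()
    if pc_scores is None:
        _, pc_scores = fit_pca(profiles)
    permissive_idx, clusterable_idx = split_permissive(
        profiles, params.permissive_threshold
    )
    labels = pd.Series("", index=profiles.index, dtype=object)
    labels.loc[permissive_idx] = [
        f"{wt}P" for wt in permissive_idx.get_level_values("wt_aa")
    ]
    pc_cols = params.pc_columns()
    clusterable_wt = clusterable_idx.get_level_values("wt_aa")
    for aa in sorted(set(clusterable_wt)):
        idx_aa = clusterable_idx[clusterable_wt == aa]
        pcs = pc_scores.loc[idx_aa, pc_cols].to_numpy(dtype=float)
        ids = cluster_amino_acid(pcs, params, params.deep_split_for(aa))
        labels.loc[idx_aa] = label_subtypes(aa, ids, pcs)
    out = labels.rename("label").reset_index()
    return out


def subtype_mean_profiles(
    assignments: pd.DataFrame, profiles: ProfileSet
) -> pd.DataFrame:
    """Mean ER profile, size and within-amino-acid frequency of every subtype.

    Frequency is size divided by the total number of positions of that
    subtype's amino acid (permissive and outlier positions included in the
    denominator); frequencies of one amino acid's labels sum to 1.
    """
    labels = pd.Series(
        assignments["label"].to_numpy(), index=profiles.index, name="label"
    )
    means = profiles.er.groupby(labels).mean()
    sizes = labels.value_counts().sort_index()
    aa_of_label = means.index.str[0]
    totals = labels.str[0].value_counts()
    out = means.copy()
    out.insert(0, "size", sizes.loc[means.index].to_numpy())
    out.insert(1, "frequency", out["size"] / aa_of_label.map(totals).to_numpy())
    out.index.name = "label"
    return out.sort_index()


def correlate_subtypes(
    subtype_profiles: pd.DataFrame,
) -> tuple[pd.DataFrame, list[str]]:
    """Pearson correlation between subtype mean profiles + average-linkage order.

    Returns the correlation matrix (labels x labels) and the dendrogram leaf
    order on distance ``1 - r``, used to group subtypes with similar profile
    shapes across amino acids.
    """
    er_cols = [c for c in subtype_profiles.columns if c in set(AA_ORDER)]
    X = subtype_profiles[er_cols].to_numpy(dtype=float)
    labels = list(subtype_profiles.index)
    if len(labels) < 2:
        raise ValueError("need at least 2 subtypes to correlate")
    sd = X.std(axis=1)
    if (sd == 0).any():
        bad = labels[int(np.argmax(sd == 0))]
        raise ValueError(f"subtype {bad} has a constant mean profile; correlation undefined")
    corr = np.corrcoef(X)
    dist = squareform(1.0 - corr, checks=False)
    Z = hierarchy.linkage(dist, method="average")
    order = [labels[i] for i in hierarchy.leaves_list(Z)]
    corr_df = pd.DataFrame(corr, index=labels, columns=labels)
    return corr_df, order


def count_numbered_subtypes(labels) -> int:
    """Number of distinct numbered (non-permissive, non-outlier) subtypes."""
    return len({l for l in labels if l and l[1:].isdigit()})


def saturation_analysis(
    profiles: ProfileSet,
    params: ClusteringParams | None = None,
    start: int = 1000,
    step: int = 200,
    n_shuffles: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Subtype counts on growing random subsets of the landscape.

    For each of ``n_shuffles`` seeded position shuffles, the full pipeline
    (PCA refit on the subset, then clustering) runs on the first ``size``
    positions for ``size = start, start+step, ...`` up to the full landscape,
    and the numbered subtypes are counted. A plateau indicates the catalogue
    has saturated at the data's intrinsic number of subtypes.
    """
    params = params or ClusteringParams()
    n = len(profiles)
    if start > n:
        raise ValueError(f"start ({start}) exceeds number of positions ({n})")
    sizes = list(range(start, n + 1, step))
    if sizes[-1] != n:
        sizes.append(n)
    rows = []
    for shuffle_id in range(n_shuffles):
        rng = np.random.default_rng([seed, shuffle_id])
        perm = rng.permutation(n)
        for size in sizes:
            subset = profiles.index[np.sort(perm[:size])]
            sub = profiles.subset(subset)
            assignments = assign_subtypes(sub, params)
            rows.append((size, shuffle_id, count_numbered_subtypes(assignments["label"])))
    return pd.DataFrame(rows, columns=["size", "shuffle", "n_subtypes"])


def most_selective_subtype(
    subtype_profiles: pd.DataFrame, highest: bool = False
) -> pd.Series:
    """The numbered subtype with the most negative overall mean ER per amino acid.

    With ``highest=True`` the rule flips to the largest mean ER. Amino acids
    with no numbered subtype get a missing value.
    """
    er_cols = [c for c in subtype_profiles.columns if c in set(AA_ORDER)]
    numbered = subtype_profiles[subtype_profiles.index.str[1:].str.isdigit()]
    result: dict[str, str] = {}
    for aa in AA_ORDER:
        rows = numbered[numbered.index.str[0] == aa]
        if rows.empty:
            continue
        overall = rows[er_cols].mean(axis=1)
        result[aa] = overall.idxmax() if highest else overall.idxmin()
    return pd.Series(result, dtype=object).reindex(list(AA_ORDER))
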