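"""Project new studies onto a stored reference landscape.

A :class:`ReferenceBundle` freezes everything needed to place positions of
a freshly normalized study into an existing landscape: the PCA basis, the
(seeded) UMAP transformer, per-subtype centroids in PC2-PC20 space with an
assignment radius, the imputation medians of the reference dataset, and the
permissive threshold. New positions are imputed with the *reference*
medians, projected through the stored basis, and assigned the nearest
same-amino-acid subtype centroid by cosine distance — or the permissive /
outlier label when the permissive rule or the centroid radius says so.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import AA_ORDER
from .ingest import ProfileSet, impute_missing
from .landscape import PC_COLUMNS, PCAModel, fit_umap
from .subtypes import ClusteringParams, cosine_distance


@dataclass
class SubtypeCentroid:
    label: str
    centroid: np.ndarray  # PC2..PC20 mean of member positions
    radius: float  # assignment radius: percentile of member-to-centroid cosine distance
    size: int


@dataclass
class ReferenceBundle:
    """Everything needed to project and classify positions of a new study."""

    pca: PCAModel
    centroids: dict[str, SubtypeCentroid]
    medians: dict[tuple[str, str], float]
    permissive_threshold: float = 0.4
    pc_range: tuple[int, int] = (2, 20)
    umap_params: dict = field(default_factory=lambda: {"n_neighbors": 15, "min_dist": 0.1})
    umap_seed: int = 0
    umap_training: np.ndarray | None = None
    known_amino_acids: tuple[str, ...] = ()
    _umap_reducer: object | None = field(default=None, repr=False)

    def pc_slice(self) -> slice:
        lo, hi = self.pc_range
        return slice(lo - 1, hi)

    def amino_acids(self) -> set[str]:
        return set(self.known_amino_acids) | {label[0] for label in self.centroids}

    def umap_reducer(self):
        """The fitted UMAP transformer, re-fit deterministically on demand."""
        if self._umap_reducer is None:
            if self.umap_training is None:
                raise ValueError("bundle has no UMAP training data")
            _, reducer = fit_umap(
                self.umap_training, seed=self.umap_seed, **self.umap_params
            )
            self._umap_reducer = reducer
        return self._umap_reducer

    # -- serialization: one JSON + a TSV sidecar for the UMAP training matrix

    def save(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        data = {
            "pca": {
                "center": self.pca.center.tolist(),
                "loadings_row_major": self.pca.loadings.tolist(),
                "explained_variance": self.pca.explained_variance.tolist(),
            },
            "centroids": {
                label: {
                    "centroid": c.centroid.tolist(),
                    "radius": c.radius,
                    "size": c.size,
                }
                for label, c in self.centroids.items()
            },
            "medians": {f"{wt}>{mut}": v for (wt, mut), v in self.medians.items()},
            "permissive_threshold": self.permissive_threshold,
            "pc_range": list(self.pc_range),
            "umap_params": self.umap_params,
            "umap_seed": self.umap_seed,
            "known_amino_acids": list(self.known_amino_acids),
        }
        with open(prefix.with_suffix(".json"), "w") as fh:
            json.dump(data, fh)
        if self.umap_training is not None:
            pd.DataFrame(self.umap_training).to_csv(
                prefix.parent / (prefix.name + ".umap_training.tsv"),
                sep="\t", index=False, float_format="%.12g",
            )

    @classmethod
    def load(cls, prefix: str | Path) -> "ReferenceBundle":
        prefix = Path(prefix)
        with open(prefix.with_suffix(".json")) as fh:
            data = json.load(fh)
        pca = PCAModel(
            center=np.asarray(data["pca"]["center"], dtype=float),
            loadings=np.asarray(data["pca"]["loadings_row_major"], dtype=float),
            explained_variance=np.asarray(data["pca"]["explained_variance"], dtype=float),
        )
        centroids = {
            label: SubtypeCentroid(
                label=label,
                centroid=np.asarray(c["centroid"], dtype=float),
                radius=float(c["radius"]),
                size=int(c["size"]),
            )
            for label, c in data["centroids"].items()
        }
        medians = {
            (k.split(">")[0], k.split(">")[1]): float(v)
            for k, v in data["medians"].items()
        }
        training_path = prefix.parent / (prefix.name + ".umap_training.tsv")
        training = (
            pd.read_csv(training_path, sep="\t").to_numpy(dtype=float)
            if training_path.exists()
            else None
        )
        return cls(
            pca=pca,
            centroids=centroids,
            medians=medians,
            permissive_threshold=float(data["permissive_threshold"]),
            pc_range=tuple(data["pc_range"]),
            umap_params=data["umap_params"],
            umap_seed=int(data["umap_seed"]),
            umap_training=training,
            known_amino_acids=tuple(data.get("known_amino_acids", ())),
        )


def build_reference_bundle(
    profiles: ProfileSet,
    pca: PCAModel,
    pc_scores: pd.DataFrame,
    assignments: pd.DataFrame,
    medians: dict[tuple[str, str], float],
    params: ClusteringParams | None = None,
    radius_percentile: float = 100.0,
    umap_seed: int = 0,
    umap_params: dict | None = None,
) -> ReferenceBundle:
    """Freeze a fitted landscape + subtype catalogue into a reference bundle.

    Each numbered subtype gets the mean of its members' PC2-PC20 scores as a
    centroid and the ``radius_percentile``-th percentile of member-to-centroid
    cosine distances as its assignment radius. The default (100, i.e. the
    farthest member) keeps every reference member inside its own subtype's
    radius; lower it to treat the subtype's most peripheral members as
    outliers too.
    """
    params = params or ClusteringParams()
    pc_cols = params.pc_columns()
    labels = pd.Series(assignments["label"].to_numpy(), index=profiles.index)
    centroids: dict[str, SubtypeCentroid] = {}
    for label, idx in labels.groupby(labels).groups.items():
        if not label[1:].isdigit():
            continue
        pcs = pc_scores.loc[idx, pc_cols].to_numpy(dtype=float)
        centroid = pcs.mean(axis=0)
        dists = np.array([cosine_distance(row, centroid) for row in pcs])
        centroids[label] = SubtypeCentroid(
            label=label,
            centroid=centroid,
            radius=float(np.percentile(dists, radius_percentile)),
            size=len(idx),
        )
    return ReferenceBundle(
        pca=pca,
        centroids=centroids,
        medians=medians,
        permissive_threshold=params.permissive_threshold,
        pc_range=params.pc_range,
        umap_params=umap_params or {"n_neighbors": 15, "min_dist": 0.1},
        umap_seed=umap_seed,
        umap_training=profiles.er.to_numpy(dtype=float),
        known_amino_acids=tuple(
            sorted(set(profiles.index.get_level_values("wt_aa")))
        ),
    )


def impute_with_reference(table: pd.DataFrame, bundle: ReferenceBundle) -> ProfileSet:
    """Complete a normalized study table using the bundle's stored medians."""
    return impute_missing(table, medians=bundle.medians)


def project_positions(
    profiles: ProfileSet, bundle: ReferenceBundle, umap: bool = True
) -> pd.DataFrame:
    """PC scores (and optionally UMAP coordinates) of new positions."""
    X = profiles.er.to_numpy(dtype=float)
    scores = bundle.pca.transform(X)
    out = pd.DataFrame(scores, index=profiles.index, columns=PC_COLUMNS)
    if umap:
        emb = bundle.umap_reducer().transform(X)
        out["umap1"] = np.asarray(emb)[:, 0]
        out["umap2"] = np.asarray(emb)[:, 1]
    return out.reset_index()


def assign_subtype(
    er_vector: np.ndarray, wt_aa: str, bundle: ReferenceBundle
) -> str:
    """Predict the subtype of one normalized, imputed profile.

    Permissive rule first; otherwise nearest same-amino-acid centroid by
    cosine distance in PC2-PC20 space, demoted to the outlier label when the
    distance exceeds that subtype's assignment radius. The returned label
    always carries the query's wild-type amino acid.
    """
    if wt_aa not in bundle.amino_acids():
        raise ValueError(f"amino acid {wt_aa!r} absent from the reference bundle")
    er_vector = np.asarray(er_vector, dtype=float)
    if np.abs(er_vector).max() < bundle.permissive_threshold:
        return f"{wt_aa}P"
    pcs = bundle.pca.transform(er_vector[None, :])[0][bundle.pc_slice()]
    best_label, best_dist = None, np.inf
    for label, c in sorted(bundle.centroids.items()):
        if label[0] != wt_aa:
            continue
        d = cosine_distance(pcs, c.centroid)
        if d < best_dist:
            best_label, best_dist = label, d
    if best_label is None or best_dist > bundle.centroids[best_label].radius:
        return f"{wt_aa}O"
    return best_label


def assign_subtypes_frame(profiles: ProfileSet, bundle: ReferenceBundle) -> pd.DataFrame:
    """Vectorized convenience: assign_subtype over a whole ProfileSet."""
    wts = profiles.index.get_level_values("wt_aa")
    X = profiles.er.to_numpy(dtype=float)
    labels = [assign_subtype(X[i], wts[i], bundle) for i in range(len(X))]
    out = pd.DataFrame(index=profiles.index).assign(label=labels)
    return out.reset_index()
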