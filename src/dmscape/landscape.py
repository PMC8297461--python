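"""The combined mutational landscape: PCA, UMAP embedding and summaries.

The landscape treats each position's 20-entry normalized ER profile as a
point in R^20. PCA is fit across the whole landscape; PC1 tracks overall
mutational tolerance (it is essentially the mean normalized ER of the
position), while PC2 onwards capture the *pattern* of which substitutions
are tolerated — the signal the subtype clustering runs on. UMAP provides a
2-D visual embedding of the same profiles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import AA_ORDER
from .ingest import ProfileSet

PC_COLUMNS = [f"PC{i}" for i in range(1, 21)]


@dataclass
class PCAModel:
    """Principal components of the landscape profiles.

    ``loadings`` columns are PC1..PC20, orthonormal; each column's sign is
    fixed so that its largest-magnitude element is positive, making the model
    stable under refitting and serialization. ``explained_variance`` is the
    (ddof=1) variance of each score column, non-increasing.
    """

    center: np.ndarray
    loadings: np.ndarray
    explained_variance: np.ndarray

    def transform(self, profiles: np.ndarray) -> np.ndarray:
        return (np.asarray(profiles, dtype=float) - self.center) @ self.loadings

    def inverse_transform(self, scores: np.ndarray) -> np.ndarray:
        return np.asarray(scores, dtype=float) @ self.loadings.T + self.center

    def to_json(self, path: str | Path) -> None:
        data = {
            "center": self.center.tolist(),
            "loadings_row_major": self.loadings.tolist(),
            "explained_variance": self.explained_variance.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(data, fh)

    @classmethod
    def from_json(cls, path: str | Path) -> "PCAModel":
        with open(path) as fh:
            data = json.load(fh)
        return cls(
            center=np.asarray(data["center"], dtype=float),
            loadings=np.asarray(data["loadings_row_major"], dtype=float),
            explained_variance=np.asarray(data["explained_variance"], dtype=float),
        )


def fit_pca(profiles: ProfileSet | np.ndarray) -> tuple[PCAModel, pd.DataFrame]:
    """Fit full-rank (20-component) PCA to the landscape profiles.

    Returns the model and per-position scores (columns PC1..PC20). The fit is
    exact: reconstruction from all 20 components reproduces the input to
    numerical precision.
    """
    from sklearn.decomposition import PCA

    if isinstance(profiles, ProfileSet):
        X = profiles.er.to_numpy(dtype=float)
        index = profiles.er.index
    else:
        X = np.asarray(profiles, dtype=float)
        index = pd.RangeIndex(len(X))
    if X.shape[0] <= X.shape[1]:
        raise ValueError(
            f"need more profiles ({X.shape[0]}) than dimensions ({X.shape[1]}) to fit the PCA"
        )
    pca = PCA(n_components=X.shape[1], svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.T.copy()
    # deterministic sign: largest-magnitude element of each component positive
    flip = np.array(
        [np.sign(col[np.argmax(np.abs(col))]) or 1.0 for col in loadings.T]
    )
    loadings *= flip
    scores *= flip
    model = PCAModel(
        center=pca.mean_.copy(),
        loadings=loadings,
        explained_variance=pca.explained_variance_.copy(),
    )
    return model, pd.DataFrame(scores, index=index, columns=PC_COLUMNS)


def fit_umap(
    X: ProfileSet | np.ndarray | pd.DataFrame,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    seed: int = 0,
):
    """Fit a 2-D UMAP embedding of the profiles.

    Returns ``(embedding, reducer)``; the fitted reducer supports
    out-of-sample projection of new points via ``reducer.transform``. With a
    fixed ``seed`` the embedding is deterministic.
    """
    import umap

    if isinstance(X, ProfileSet):
        X = X.er.to_numpy(dtype=float)
    elif isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if n_neighbors >= len(X):
        raise ValueError(f"n_neighbors ({n_neighbors}) must be < number of points ({len(X)})")
    reducer = umap.UMAP(
        n_components=2, n_neighbors=n_neighbors, min_dist=min_dist, random_state=seed
    )
    embedding = reducer.fit_transform(X)
    return np.asarray(embedding, dtype=float), reducer


def mean_er(profiles: ProfileSet | np.ndarray) -> np.ndarray:
    """Mean normalized ER per position: arithmetic mean of the 20 profile entries."""
    X = profiles.er.to_numpy(dtype=float) if isinstance(profiles, ProfileSet) else np.asarray(profiles, dtype=float)
    return X.mean(axis=1)


def substitution_type_means(profiles: ProfileSet) -> pd.DataFrame:
    """20x20 table of mean ER per substitution type (rows wt, columns target).

    The diagonal is the mean synonymous score. Cells with no position of that
    wild type anywhere are NaN.
    """
    wt = profiles.index.get_level_values("wt_aa")
    table = profiles.er.groupby(wt).mean()
    return table.reindex(index=list(AA_ORDER), columns=list(AA_ORDER))


def mean_er_away(profiles: ProfileSet) -> pd.Series:
    """Mean ER of all *missense* substitutions away from each wild-type amino acid.

    The synonymous (wild-type) entry is excluded from each position's mean.
    """
    X = profiles.er.to_numpy(dtype=float)
    wt = profiles.index.get_level_values("wt_aa").to_numpy()
    aa_to_col = {aa: j for j, aa in enumerate(AA_ORDER)}
    wt_cols = np.array([aa_to_col[a] for a in wt])
    totals = X.sum(axis=1) - X[np.arange(len(X)), wt_cols]
    per_pos = totals / 19.0
    return pd.Series(per_pos).groupby(pd.Series(wt)).mean().reindex(list(AA_ORDER))


def aggregate_position_annotations(annotations: pd.DataFrame) -> pd.DataFrame:
    """Average per-substitution annotation terms over each position.

    ``annotations`` has rows keyed (gene, position, mut_aa, term, value);
    returns one mean per (gene, position, term), e.g. the average ΔΔG
    component across all substitutions at a position.
    """
    if annotations.empty:
        return pd.DataFrame(columns=["gene", "position", "term", "value"])
    return (
        annotations.groupby(["gene", "position", "term"], as_index=False)["value"]
        .mean()
    )


def blosum62_correlation(type_means: pd.DataFrame) -> float:
    """Pearson correlation between mean missense ER per substitution type and
    the corresponding BLOSUM62 entries (off-diagonal cells with data).

    A convenience yardstick against evolutionary substitution preferences.
    """
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")
    xs, ys = [], []
    for a in AA_ORDER:
        for b in AA_ORDER:
            if a == b:
                continue
            v = type_means.loc[a, b]
            if pd.notna(v):
                xs.append(float(v))
                ys.append(float(blosum[a][b]))
    if len(xs) < 3:
        raise ValueError("too few substitution types with data for a correlation")
    return float(np.corrcoef(xs, ys)[0, 1])


def landscape_table(
    profiles: ProfileSet,
    pc_scores: pd.DataFrame,
    embedding: np.ndarray,
) -> pd.DataFrame:
    """Per-position landscape summary: key, mean ER, PC scores, UMAP coordinates."""
    out = pc_scores.copy()
    out.insert(0, "mean_er", mean_er(profiles))
    out["umap1"] = embedding[:, 0]
    out["umap2"] = embedding[:, 1]
    return out.reset_index()
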