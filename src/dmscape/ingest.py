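"""Normalize heterogeneous DMS studies onto a common enrichment-ratio scale.

The pipeline order is fixed:

    transform_scores -> average_replicates -> collapse_multimutants
        -> normalize_study -> filter_positions -> impute_missing

Variant tables are tidy :class:`pandas.DataFrame` objects with columns
``study, gene, substitutions, score, replicate, condition`` where
``substitutions`` is a semicolon-joined string of compact tokens such as
``"A123C"`` / ``"Q45*"`` / ``"K9="`` (see :mod:`dmscape.io` for parsing).
Normalized single-substitution tables carry one row per
``(study, gene, position, mut_aa)`` with a normalized ``er`` score:
negative is deleterious, zero neutral, positive advantageous.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import AA_ORDER, AA_SET, NONSENSE, SYNONYMOUS

VARIANT_COLUMNS = ["study", "gene", "substitutions", "score", "replicate", "condition"]
NORMALIZED_COLUMNS = ["study", "gene", "position", "wt_aa", "mut_aa", "er", "measured"]

#: index levels identifying one position of one study
POSITION_KEY = ["study", "gene", "position", "wt_aa"]


class IngestError(ValueError):
    """Raised for malformed inputs or degenerate studies."""


@dataclass
class StudyConfig:
    """Declarative recipe turning one study's raw scores into log2 ER scores.

    Parameters
    ----------
    transform:
        ``identity`` (scores already log2 ER), ``log2_ratio`` (scores are
        positive ratios relative to wild type), ``negate`` (sign-flipped
        log2 ER, e.g. depletion scores) or ``affine`` (``a * score + b``
        with coefficients in :attr:`affine`).
    condition_policy:
        Mapping ``condition_id -> {"average", "prefer", "drop"}``. If any
        condition is marked ``prefer``, only preferred conditions are kept;
        otherwise all conditions not marked ``drop`` are averaged.
        An empty mapping averages every condition.
    multimutant_cap:
        Sequences with more substitutions than this never contribute to a
        collapsed single-substitution score.
    """

    study_id: str
    gene: str
    transform: str = "identity"
    affine: tuple[float, float] | None = None
    condition_policy: dict[str, str] = field(default_factory=dict)
    multimutant_cap: int | None = 3
    wt_aa_map: dict[int, str] | None = None
    include: bool = True

    _TRANSFORMS = ("identity", "log2_ratio", "negate", "affine")
    _POLICIES = ("average", "prefer", "drop")

    def __post_init__(self) -> None:
        if self.transform not in self._TRANSFORMS:
            raise IngestError(
                f"unknown transform {self.transform!r}; expected one of {self._TRANSFORMS}"
            )
        if self.transform == "affine" and self.affine is None:
            raise IngestError("transform 'affine' requires coefficients (a, b)")
        for cond, policy in self.condition_policy.items():
            if policy not in self._POLICIES:
                raise IngestError(
                    f"condition {cond!r}: unknown policy {policy!r}; expected one of {self._POLICIES}"
                )
        if self.multimutant_cap is not None and self.multimutant_cap < 1:
            raise IngestError("multimutant_cap must be >= 1")


def transform_scores(records: pd.DataFrame, config: StudyConfig) -> pd.DataFrame:
    """Put raw study scores onto the common log2 enrichment-ratio scale.

    A variant behaving exactly as wild type maps to 0. All transforms are
    monotone, so score ranking within the study is preserved (up to sign for
    ``negate``, which is applied precisely to restore the common orientation).
    """
    out = records.copy()
    score = out["score"].astype(float)
    if config.transform == "identity":
        out["score"] = score
    elif config.transform == "log2_ratio":
        bad = score <= 0
        if bad.any():
            row = out[bad].iloc[0]
            raise IngestError(
                f"log2_ratio requires positive ratios; got {row['score']!r} for "
                f"{row['study']}:{row['substitutions']}"
            )
        out["score"] = np.log2(score)
    elif config.transform == "negate":
        out["score"] = -score
    elif config.transform == "affine":
        a, b = config.affine  # type: ignore[misc]
        out["score"] = a * score + b
    return out


def average_replicates(records: pd.DataFrame, config: StudyConfig) -> pd.DataFrame:
    """Average replicate and comparable-condition measurements per variant.

    Conditions marked ``drop`` are excluded; if any condition is marked
    ``prefer``, only preferred conditions are retained. The surviving
    measurements are averaged arithmetically per (gene, substitutions).
    """
    df = records.copy()
    df["condition"] = df["condition"].fillna("").astype(str)
    policy = config.condition_policy
    if policy:
        preferred = {c for c, p in policy.items() if p == "prefer"}
        dropped = {c for c, p in policy.items() if p == "drop"}
        if preferred:
            df = df[df["condition"].isin(preferred)]
        else:
            df = df[~df["condition"].isin(dropped)]
    if df.empty:
        raise IngestError(
            f"study {config.study_id!r}: condition policy retains no measurements"
        )
    grouped = (
        df.groupby(["study", "gene", "substitutions"], as_index=False, sort=True)["score"]
        .mean()
    )
    grouped["replicate"] = ""
    grouped["condition"] = ""
    return grouped[VARIANT_COLUMNS]


def _split_tokens(substitutions: str) -> list[str]:
    return [t for t in str(substitutions).split(";") if t]


def collapse_multimutants(records: pd.DataFrame, cap: int | None) -> pd.DataFrame:
    """Reduce multi-mutant sequences to single-substitution scores.

    Directly measured single substitutions are kept verbatim. A substitution
    seen only inside multi-mutant sequences receives the mean score of all
    sequences containing it with at most ``cap`` substitutions; substitutions
    occurring only in sequences above the cap are absent from the output.

    Returns a table with columns ``study, gene, position, wt_aa, mut_aa, score``.
    """
    from .io import parse_substitution_token  # local import; io depends on ingest types

    if cap is not None and cap < 1:
        raise IngestError("multimutant cap must be >= 1")

    direct: dict[tuple, float] = {}
    pooled: dict[tuple, list[float]] = {}
    for row in records.itertuples(index=False):
        tokens = _split_tokens(row.substitutions)
        subs = [parse_substitution_token(t) for t in tokens]
        if len(subs) == 1:
            pos, wt, mut = subs[0]
            direct[(row.study, row.gene, pos, wt, mut)] = float(row.score)
        else:
            if cap is not None and len(subs) > cap:
                continue
            for pos, wt, mut in subs:
                pooled.setdefault((row.study, row.gene, pos, wt, mut), []).append(
                    float(row.score)
                )

    rows = []
    for key, score in direct.items():
        rows.append((*key, score))
    for key, scores in pooled.items():
        if key not in direct:
            rows.append((*key, float(np.mean(scores))))
    out = pd.DataFrame(
        rows, columns=["study", "gene", "position", "wt_aa", "mut_aa", "score"]
    )
    return out.sort_values(["study", "gene", "position", "mut_aa"]).reset_index(drop=True)


def normalize_study(scores: pd.DataFrame) -> pd.DataFrame:
    """Normalize one study's log2 ER scores by its deleterious tail.

    Every score is divided by the magnitude of the median of the lowest 10%
    of nonsynonymous scores (the ``ceil(0.1 * n)`` smallest values), so the
    worst substitutions — typically nonsense mutations, assumed to represent
    complete loss of function — land around -1 on the common scale. Division
    by the magnitude (not the signed median, which is negative in any real
    study) preserves the sign convention: negative remains deleterious.

    Synonymous scores are carried through the same division but excluded
    from the tail pool.
    """
    nonsyn = scores[scores["mut_aa"] != SYNONYMOUS]
    n = len(nonsyn)
    if n < 10:
        raise IngestError(f"need >= 10 nonsynonymous scores to normalize, got {n}")
    k = math.ceil(0.1 * n)
    tail = np.sort(nonsyn["score"].to_numpy(dtype=float))[:k]
    m = float(np.median(tail))
    if m == 0.0:
        raise IngestError("degenerate study: no deleterious tail (bottom-decile median is 0)")
    out = scores.copy()
    out["er"] = out["score"].astype(float) / abs(m)
    out["measured"] = True
    return out[NORMALIZED_COLUMNS]


def count_nonsyn_measured(table: pd.DataFrame) -> pd.Series:
    """Measured missense+nonsense entries per position (0-20; synonymous excluded)."""
    nonsyn = table[(table["mut_aa"] != SYNONYMOUS) & table["measured"]]
    nonsyn = nonsyn[nonsyn["mut_aa"] != nonsyn["wt_aa"]]
    return nonsyn.groupby(POSITION_KEY).size()


def filter_positions(table: pd.DataFrame, min_measured: int = 15) -> pd.DataFrame:
    """Drop positions with fewer than ``min_measured`` of the 20 possible
    missense + nonsense substitutions measured (synonymous does not count).

    Scores are never altered, only whole positions removed.
    """
    if table.empty:
        return table.copy()
    counts = count_nonsyn_measured(table)
    keep = counts[counts >= min_measured].index
    idx = pd.MultiIndex.from_frame(table[POSITION_KEY])
    return table[idx.isin(keep)].reset_index(drop=True)


@dataclass
class ProfileSet:
    """Complete mutational profiles, one row per (study, gene, position, wt_aa).

    ``er`` holds the 20-entry profile (columns in :data:`AA_ORDER`; the
    wild-type column is the synonymous score), ``nonsense`` the stop-codon ER
    (NaN when unmeasured and unimputable), ``imputed`` marks entries filled by
    imputation, and ``n_measured`` counts experimentally measured missense +
    nonsense entries per position (max 20).
    """

    er: pd.DataFrame
    nonsense: pd.Series
    imputed: pd.DataFrame
    n_measured: pd.Series

    def __post_init__(self) -> None:
        assert list(self.er.columns) == list(AA_ORDER)

    def __len__(self) -> int:
        return len(self.er)

    @property
    def index(self) -> pd.MultiIndex:
        return self.er.index

    @property
    def wt_aa(self) -> pd.Series:
        return self.index.get_level_values("wt_aa").to_series(index=self.index)

    def measured_fraction(self) -> float:
        """Fraction of nonsynonymous er_vector + nonsense entries that were measured."""
        per_pos = self.n_measured.to_numpy(dtype=float)
        return float(per_pos.sum() / (20.0 * len(per_pos)))

    def subset(self, positions) -> "ProfileSet":
        return ProfileSet(
            er=self.er.loc[positions],
            nonsense=self.nonsense.loc[positions],
            imputed=self.imputed.loc[positions],
            n_measured=self.n_measured.loc[positions],
        )

    def to_frame(self) -> pd.DataFrame:
        """Wide per-position table (er columns, nonsense, mask, n_measured)."""
        wide = self.er.copy()
        wide.columns = [f"er_{aa}" for aa in AA_ORDER]
        wide["nonsense_er"] = self.nonsense
        for aa in AA_ORDER:
            wide[f"imputed_{aa}"] = self.imputed[aa].astype(int)
        wide["n_nonsyn_measured"] = self.n_measured
        return wide.reset_index()

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ProfileSet":
        idx = pd.MultiIndex.from_frame(frame[POSITION_KEY])
        er = pd.DataFrame(
            {aa: frame[f"er_{aa}"].to_numpy(dtype=float) for aa in AA_ORDER}, index=idx
        )
        imputed = pd.DataFrame(
            {aa: frame[f"imputed_{aa}"].to_numpy(dtype=bool) for aa in AA_ORDER}, index=idx
        )
        nonsense = pd.Series(frame["nonsense_er"].to_numpy(dtype=float), index=idx)
        n_meas = pd.Series(frame["n_nonsyn_measured"].to_numpy(dtype=int), index=idx)
        return cls(er=er, nonsense=nonsense, imputed=imputed, n_measured=n_meas)


def substitution_type_medians(tables: pd.DataFrame) -> dict[tuple[str, str], float]:
    """Median normalized ER per substitution type (wt -> mut), pooled across studies.

    Used as the imputation value for missing entries of that type.
    """
    measured = tables[tables["measured"]]
    nonsyn = measured[measured["mut_aa"] != SYNONYMOUS]
    med = nonsyn.groupby(["wt_aa", "mut_aa"])["er"].median()
    return {k: float(v) for k, v in med.items()}


def impute_missing(
    tables: pd.DataFrame | list[pd.DataFrame],
    medians: dict[tuple[str, str], float] | None = None,
) -> ProfileSet:
    """Fill missing entries and assemble complete 20-entry profiles.

    Missing missense/nonsense entries take the median normalized score of
    that substitution type (A -> C, A -> D, ...) pooled across all supplied
    studies (or the precomputed ``medians``, e.g. from a stored reference);
    missing synonymous entries are set to 0, reflecting that measured
    synonymous scores cluster tightly around zero.
    """
    if isinstance(tables, list):
        tables = pd.concat(tables, ignore_index=True)
    if medians is None:
        medians = substitution_type_medians(tables)

    # wt consistency check within a position
    dup = tables.groupby(POSITION_KEY[:3])["wt_aa"].nunique()
    if (dup > 1).any():
        bad = dup[dup > 1].index[0]
        raise IngestError(f"conflicting wild-type amino acids at {bad}")

    idx = pd.MultiIndex.from_frame(
        tables[POSITION_KEY].drop_duplicates().reset_index(drop=True)
    )
    measured = tables[tables["measured"]]
    pivot = measured.pivot_table(
        index=POSITION_KEY, columns="mut_aa", values="er", aggfunc="mean"
    ).reindex(idx)

    n_pos = len(idx)
    er = np.empty((n_pos, 20))
    imputed = np.zeros((n_pos, 20), dtype=bool)
    nonsense = np.full(n_pos, np.nan)
    n_meas = np.zeros(n_pos, dtype=int)

    cols = {aa: pivot[aa].to_numpy() if aa in pivot else np.full(n_pos, np.nan) for aa in AA_ORDER}
    syn_col = pivot[SYNONYMOUS].to_numpy() if SYNONYMOUS in pivot else np.full(n_pos, np.nan)
    stop_col = pivot[NONSENSE].to_numpy() if NONSENSE in pivot else np.full(n_pos, np.nan)
    wts = idx.get_level_values("wt_aa").to_numpy()

    missing_types: set[tuple[str, str]] = set()
    for j, aa in enumerate(AA_ORDER):
        col = cols[aa]
        for i in range(n_pos):
            wt = wts[i]
            if aa == wt:
                v = syn_col[i]
                if np.isnan(v):
                    er[i, j] = 0.0
                    imputed[i, j] = True
                else:
                    er[i, j] = v
            else:
                v = col[i]
                if np.isnan(v):
                    key = (wt, aa)
                    if key not in medians:
                        missing_types.add(key)
                        er[i, j] = np.nan
                    else:
                        er[i, j] = medians[key]
                    imputed[i, j] = True
                else:
                    er[i, j] = v
                    n_meas[i] += 1
    if missing_types:
        pretty = ", ".join(f"{a}->{b}" for a, b in sorted(missing_types))
        raise IngestError(
            f"cannot impute: no measured instances anywhere for substitution type(s) {pretty}"
        )
    for i in range(n_pos):
        v = stop_col[i]
        if np.isnan(v):
            key = (wts[i], NONSENSE)
            nonsense[i] = medians.get(key, np.nan)
        else:
            nonsense[i] = v
            n_meas[i] += 1

    return ProfileSet(
        er=pd.DataFrame(er, index=idx, columns=list(AA_ORDER)),
        nonsense=pd.Series(nonsense, index=idx),
        imputed=pd.DataFrame(imputed, index=idx, columns=list(AA_ORDER)),
        n_measured=pd.Series(n_meas, index=idx),
    )


def process_study(records: pd.DataFrame, config: StudyConfig) -> pd.DataFrame:
    """Run one study through transform -> average -> collapse -> normalize."""
    if config.wt_aa_map:
        from .io import parse_substitution_token

        for row in records.itertuples(index=False):
            for token in _split_tokens(row.substitutions):
                pos, wt, _ = parse_substitution_token(token)
                declared = config.wt_aa_map.get(pos)
                if declared is not None and declared != wt:
                    warnings.warn(
                        f"study {config.study_id}: wild-type mismatch at position {pos} "
                        f"({wt} vs declared {declared}); keeping the study's own wild type",
                        stacklevel=2,
                    )
    step = transform_scores(records, config)
    step = average_replicates(step, config)
    singles = collapse_multimutants(step, config.multimutant_cap)
    return normalize_study(singles)


def combine_studies(
    normalized: list[pd.DataFrame], min_measured: int = 15
) -> tuple[pd.DataFrame, ProfileSet]:
    """Concatenate normalized studies, filter sparse positions, impute gaps.

    Returns the filtered long-format combined table and the complete
    :class:`ProfileSet`. Positions covered by several studies stay separate,
    keyed by study_id.
    """
    combined = pd.concat(normalized, ignore_index=True)
    filtered = filter_positions(combined, min_measured=min_measured)
    profiles = impute_missing(filtered)
    return filtered, profiles
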