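"""Synthetic DMS studies with planted subtype structure.

The generator emulates the features of curated deep mutational scans that
the pipeline must undo or tolerate: per-position profiles drawn from
amino-acid-specific archetypes, a multiplicative per-study scale (removed by
tail normalization), replicate noise, missing entries, strongly negative
nonsense scores, and optional multi-mutant sequences with approximately
additive effects. Every draw flows from the spec's seed, so a given
:class:`SyntheticSpec` is fully reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .constants import AA_ORDER, HYDROPHOBIC, NONSENSE, POLAR_CHARGED, SYNONYMOUS
from .ingest import VARIANT_COLUMNS
from .io import format_substitution


@dataclass(frozen=True)
class Archetype:
    """A recurring positional role: a template 20-entry ER profile.

    The synonymous (wild-type) slot of the template is always 0; nonsense is
    strongly negative by default, anchoring the normalization tail.
    """

    name: str
    wt_aa: str
    er_template: tuple[float, ...]
    nonsense_er: float = -1.0
    #: hard bound on |entry| of the planted profile (noise clipped to it);
    #: the permissive archetype uses 0.2 — half the permissive threshold — so
    #: planted permissive positions stay permissive through replicate noise
    #: and normalization
    max_abs: float | None = None

    def __post_init__(self) -> None:
        if len(self.er_template) != 20:
            raise ValueError("er_template must have 20 entries")
        wt_idx = AA_ORDER.index(self.wt_aa)
        if self.er_template[wt_idx] != 0.0:
            raise ValueError(f"archetype {self.name}: synonymous slot must be 0")

    @property
    def template(self) -> np.ndarray:
        return np.asarray(self.er_template, dtype=float)


def _template(wt_aa: str, tolerated: set[str], depth: float = -1.0) -> tuple[float, ...]:
    vec = [0.0 if aa in tolerated or aa == wt_aa else depth for aa in AA_ORDER]
    return tuple(vec)


def default_archetypes(wt_aa: str) -> list[Archetype]:
    """The default archetype library for one amino acid.

    Mirrors the recurring profile shapes seen in real landscapes: fully
    intolerant positions, positions that only reject proline (fold-topology
    sites), positions requiring the wild type's broad physicochemical class
    (hydrophobic core vs polar/charged surface), and permissive positions.
    """
    class_set = HYDROPHOBIC if wt_aa in HYDROPHOBIC else POLAR_CHARGED
    class_name = "hydrophobic-only" if wt_aa in HYDROPHOBIC else "polar-only"
    return [
        Archetype("intolerant", wt_aa, _template(wt_aa, set())),
        Archetype("not-proline", wt_aa, _template(wt_aa, set(AA_ORDER) - {"P"})),
        Archetype(class_name, wt_aa, _template(wt_aa, set(class_set))),
        Archetype(
            "permissive", wt_aa, _template(wt_aa, set(AA_ORDER)),
            nonsense_er=-1.0, max_abs=0.2,
        ),
    ]


@dataclass(frozen=True)
class StudySpec:
    study_id: str
    gene: str
    scale: float = 1.0
    n_positions: int = 200

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("study scale must be positive")


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for the generator.

    Defaults describe a realistic small meta-dataset: three studies of one
    gene each with different raw-score scales, per-entry profile noise well
    below the archetype separation, three replicates, and ~2% missing
    entries (matching the measured fraction typical of curated scans).
    """

    studies: tuple[StudySpec, ...] = (
        StudySpec("study_A", "geneA", scale=1.0, n_positions=200),
        StudySpec("study_B", "geneB", scale=2.5, n_positions=200),
        StudySpec("study_C", "geneC", scale=0.7, n_positions=200),
    )
    archetype_weights: tuple[tuple[str, float], ...] = (
        ("intolerant", 0.30),
        ("not-proline", 0.25),
        ("class", 0.25),
        ("permissive", 0.20),
    )
    noise_sd: float = 0.1
    replicate_count: int = 3
    replicate_noise_sd: float = 0.1
    missing_rate: float = 0.02
    measure_synonymous: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(w for _, w in self.archetype_weights)
        if not np.isclose(total, 1.0):
            raise ValueError(f"archetype weights must sum to 1, got {total}")
        if any(w < 0 for _, w in self.archetype_weights):
            raise ValueError("archetype weights must be non-negative")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        # 20 nonsynonymous entries per position; the position filter needs >= 15
        if self.missing_rate * 20 > 5:
            warnings.warn(
                "missing_rate leaves < 15 measured nonsynonymous entries in "
                "expectation; most positions will be filtered",
                stacklevel=2,
            )


def _resolve_archetypes(spec: SyntheticSpec, wt_aa: str) -> list[tuple[Archetype, float]]:
    library = {a.name: a for a in default_archetypes(wt_aa)}
    class_name = "hydrophobic-only" if wt_aa in HYDROPHOBIC else "polar-only"
    out = []
    for name, w in spec.archetype_weights:
        key = class_name if name == "class" else name
        if key not in library:
            raise ValueError(f"unknown archetype {name!r} for {wt_aa}")
        out.append((library[key], float(w)))
    return out


def generate_landscape(spec: SyntheticSpec) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Generate raw study tables plus the truth table of planted archetypes.

    Returns ``(tables, truth)`` where ``tables`` maps study_id to a raw
    variant table in the ingest dialect (replicated, scaled, noisy, with
    entries deleted at the missing rate) and ``truth`` records each
    position's planted archetype and its realized noise-free profile class.
    """
    rng = np.random.default_rng(spec.seed)
    tables: dict[str, pd.DataFrame] = {}
    truth_rows = []
    for study in spec.studies:
        rows = []
        for pos in range(1, study.n_positions + 1):
            wt = AA_ORDER[(pos - 1) % 20]
            pool = _resolve_archetypes(spec, wt)
            weights = np.array([w for _, w in pool])
            arch = pool[rng.choice(len(pool), p=weights / weights.sum())][0]
            noise = rng.normal(0.0, spec.noise_sd, size=20) if spec.noise_sd > 0 else np.zeros(20)
            wt_idx = AA_ORDER.index(wt)
            true_er = arch.template + noise
            if arch.max_abs is not None:
                true_er = np.clip(true_er, -arch.max_abs, arch.max_abs)
            true_er[wt_idx] = 0.0  # synonymous anchored at exactly 0
            truth_rows.append(
                (study.study_id, study.gene, pos, wt, arch.name, float(np.abs(true_er).max()))
            )
            targets = [(aa, true_er[j]) for j, aa in enumerate(AA_ORDER) if aa != wt]
            targets.append((NONSENSE, arch.nonsense_er))
            if spec.measure_synonymous:
                targets.append((SYNONYMOUS, 0.0))
            for mut, er in targets:
                if spec.missing_rate > 0 and rng.random() < spec.missing_rate:
                    continue
                raw_base = study.scale * er
                for rep in range(1, spec.replicate_count + 1):
                    jitter = (
                        rng.normal(0.0, study.scale * spec.replicate_noise_sd)
                        if spec.replicate_noise_sd > 0
                        else 0.0
                    )
                    rows.append(
                        (
                            study.study_id,
                            study.gene,
                            format_substitution(pos, wt, mut),
                            raw_base + jitter,
                            f"rep{rep}",
                            "",
                        )
                    )
        tables[study.study_id] = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    truth = pd.DataFrame(
        truth_rows,
        columns=["study", "gene", "position", "wt_aa", "archetype", "max_abs_er"],
    )
    return tables, truth


def generate_multimutants(
    singles: pd.DataFrame,
    withheld: pd.DataFrame,
    n_sequences_per_target: int = 10,
    substitutions_per_sequence: int = 2,
    epistasis_sd: float = 0.0,
    seed: int = 0,
    study_id: str = "synthetic_mm",
    gene: str = "geneA",
) -> pd.DataFrame:
    """Multi-mutant sequences whose scores are additive up to epistasis noise.

    Each withheld substitution appears in ``n_sequences_per_target``
    sequences, partnered with random directly measured substitutions at
    other positions; the sequence score is the sum of its members' single
    effects plus Gaussian epistasis noise. Averaging containing sequences
    recovers a withheld effect without bias exactly when the partners'
    effects average to zero, so recovery tests should draw partners from
    neutral substitutions.

    Both ``singles`` and ``withheld`` need columns position, wt_aa, mut_aa,
    score.
    """
    rng = np.random.default_rng(seed)
    effects = {
        (r.position, r.wt_aa, r.mut_aa): float(r.score)
        for r in pd.concat([singles, withheld]).itertuples(index=False)
    }
    partners = list(
        singles[["position", "wt_aa", "mut_aa"]].itertuples(index=False, name=None)
    )
    rows = []
    for r in withheld.itertuples(index=False):
        target = (r.position, r.wt_aa, r.mut_aa)
        for _ in range(n_sequences_per_target):
            others: list[tuple] = []
            while len(others) < substitutions_per_sequence - 1:
                cand = partners[rng.integers(len(partners))]
                if cand[0] != target[0] and all(cand[0] != o[0] for o in others):
                    others.append(cand)
            seq = sorted([target, *others])
            score = sum(effects[s] for s in seq)
            if epistasis_sd > 0:
                score += rng.normal(0.0, epistasis_sd)
            token = ";".join(format_substitution(*s) for s in seq)
            rows.append((study_id, gene, token, score, "rep1", ""))
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)


def spec_with_seed(spec: SyntheticSpec, seed: int) -> SyntheticSpec:
    return replace(spec, seed=seed)
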