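"""File dialects, configuration loading and run manifests.

Substitution tokens are accepted in two dialects and canonicalized to
compact single-letter form internally:

* compact — ``A123C`` (missense), ``Q45*`` (nonsense), ``K9=`` (synonymous)
* HGVS protein — ``p.Ala123Cys``, ``p.Gln45Ter``, ``p.Lys9=``

Coordinates are 1-based protein residue numbers throughout.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .constants import AA3_TO_1, AA_SET, NONSENSE, SYNONYMOUS
from .ingest import NORMALIZED_COLUMNS, VARIANT_COLUMNS, IngestError, StudyConfig

_COMPACT = re.compile(r"^([A-Z])(\d+)([A-Z*=])$")
_HGVS = re.compile(r"^p\.([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2}|=)$")

#: significant digits for all floating-point serialization (round-trip safe)
FLOAT_FORMAT = "%.12g"


def parse_substitution_token(token: str) -> tuple[int, str, str]:
    """Parse one substitution token into ``(position, wt_aa, mut_aa)``.

    ``mut_aa`` is ``*`` for nonsense and ``=`` for synonymous. A token whose
    wild-type and mutant letters coincide (``A123A``) is rejected: synonymous
    variants must be written explicitly with ``=``.
    """
    token = token.strip()
    m = _COMPACT.match(token)
    if m:
        wt, pos, mut = m.group(1), int(m.group(2)), m.group(3)
    else:
        m = _HGVS.match(token)
        if not m:
            raise IngestError(f"malformed substitution token {token!r}")
        wt3, pos, mut3 = m.group(1), int(m.group(2)), m.group(3)
        if wt3 not in AA3_TO_1 or wt3 == "Ter":
            raise IngestError(f"unknown wild-type residue code in {token!r}")
        wt = AA3_TO_1[wt3]
        if mut3 == SYNONYMOUS:
            mut = SYNONYMOUS
        elif mut3 in AA3_TO_1:
            mut = AA3_TO_1[mut3]
        else:
            raise IngestError(f"unknown mutant residue code in {token!r}")
    if wt not in AA_SET:
        raise IngestError(f"invalid wild-type amino acid in {token!r}")
    if mut not in AA_SET and mut not in (NONSENSE, SYNONYMOUS):
        raise IngestError(f"invalid mutant amino acid in {token!r}")
    if pos < 1:
        raise IngestError(f"position must be >= 1 in {token!r}")
    if wt == mut:
        raise IngestError(
            f"{token!r}: wild-type equals mutant; write synonymous variants as {wt}{pos}="
        )
    return pos, wt, mut


def format_substitution(position: int, wt_aa: str, mut_aa: str) -> str:
    return f"{wt_aa}{position}{mut_aa}"


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise IngestError(f"{path}: missing required column(s): {', '.join(missing)}")


def read_study_csv(path: str | Path) -> pd.DataFrame:
    """Read a raw per-study variant table (CSV or TSV by extension).

    Required columns: ``study, gene, substitutions, score``; optional
    ``replicate`` and ``condition`` default to empty. Substitution tokens in
    either dialect are canonicalized to compact form.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype={"study": str, "gene": str, "substitutions": str})
    _require_columns(df, ["study", "gene", "substitutions", "score"], path)
    for col in ("replicate", "condition"):
        if col not in df.columns:
            df[col] = ""
        df[col] = df[col].fillna("").astype(str)

    df["substitutions"] = [
        ";".join(
            format_substitution(*parse_substitution_token(t))
            for t in str(s).split(";")
            if t
        )
        for s in df["substitutions"]
    ]
    return df[VARIANT_COLUMNS]


def write_combined_tsv(table: pd.DataFrame, path: str | Path) -> None:
    """Write a normalized/combined long-format table as TSV."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_combined_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"study": str, "gene": str, "wt_aa": str, "mut_aa": str})
    _require_columns(df, NORMALIZED_COLUMNS, path)
    df["measured"] = df["measured"].astype(bool)
    return df[NORMALIZED_COLUMNS]


_CONFIG_KEYS = {
    "study_id", "gene", "transform", "affine", "condition_policy",
    "multimutant_cap", "wt_aa_map", "include",
}


def read_config_yaml(path: str | Path) -> StudyConfig:
    """Load one study configuration from YAML (strict schema)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise IngestError(f"{path}: expected a mapping at top level")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise IngestError(f"{path}: unknown configuration key(s): {', '.join(sorted(unknown))}")
    for key in ("study_id", "gene"):
        if key not in raw:
            raise IngestError(f"{path}: missing required key {key!r}")
    if raw.get("affine") is not None:
        raw["affine"] = tuple(float(x) for x in raw["affine"])
    if raw.get("wt_aa_map") is not None:
        raw["wt_aa_map"] = {int(k): str(v) for k, v in raw["wt_aa_map"].items()}
    return StudyConfig(**raw)


def write_config_yaml(config: StudyConfig, path: str | Path) -> None:
    data = asdict(config)
    if data["affine"] is not None:
        data["affine"] = list(data["affine"])
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_path: str | Path,
    command: str,
    inputs: list[str | Path] | None = None,
    config_files: list[str | Path] | None = None,
    seed: int | None = None,
) -> dict:
    """Emit a run manifest (JSON) recording command, input hashes and seed."""
    manifest = {
        "command": command,
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "seed": seed,
        "inputs": {str(p): _sha256(p) for p in (inputs or [])},
        "configs": {str(p): _sha256(p) for p in (config_files or [])},
    }
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    with open(out_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")
    return manifest
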