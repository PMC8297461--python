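#!/usr/bin/env python
"""Normalize each study onto the common ER scale and build complete profiles.

Each study is transformed, replicate-averaged, tail-normalized (bottom-decile
median scaled to -1), then the studies are combined: positions with < 15 of
20 measured nonsynonymous substitutions are dropped and remaining gaps are
imputed with substitution-type medians. Writes results/combined.tsv.
"""

from pathlib import Path

from dmscape.ingest import StudyConfig, combine_studies, process_study
from dmscape.io import read_study_csv, write_combined_tsv, write_manifest

ROOT = Path(__file__).resolve().parent.parent / "results"
GENES = {"study_A": "geneA", "study_B": "geneB", "study_C": "geneC"}

normalized = []
for study_id, gene in GENES.items():
    records = read_study_csv(ROOT / "sim" / f"{study_id}.csv")
    table = process_study(records, StudyConfig(study_id=study_id, gene=gene))
    normalized.append(table)
    print(f"{study_id}: {len(table)} normalized substitution scores")

filtered, profiles = combine_studies(normalized)
write_combined_tsv(profiles.to_frame(), ROOT / "combined.tsv")
print(
    f"combined landscape: {len(profiles)} positions, "
    f"{100 * profiles.measured_fraction():.2f}% of nonsynonymous entries measured"
)
write_manifest(
    ROOT / "combined.manifest.json", "analysis/02_normalise_combine",
    inputs=[ROOT / "sim" / f"{s}.csv" for s in GENES],
)
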