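#!/usr/bin/env python
"""Generate the synthetic multi-study DMS dataset used by the later steps.

Three studies of one gene each, with different raw-score scales (1.0, 2.5,
0.7), three replicates, 2% missing entries and planted per-amino-acid
archetypes (intolerant / not-proline / class-specific / permissive).
Writes the raw study CSVs and the planted truth table to results/sim/.
"""

import sys
from pathlib import Path

from dmscape.io import FLOAT_FORMAT, write_manifest
from dmscape.synthetic import StudySpec, SyntheticSpec, generate_landscape

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path(__file__).resolve().parent.parent / "results" / "sim"

spec = SyntheticSpec(
    studies=(
        StudySpec("study_A", "geneA", scale=1.0, n_positions=700),
        StudySpec("study_B", "geneB", scale=2.5, n_positions=700),
        StudySpec("study_C", "geneC", scale=0.7, n_positions=600),
    ),
    seed=SEED,
)
tables, truth = generate_landscape(spec)
OUT.mkdir(parents=True, exist_ok=True)
for study_id, table in tables.items():
    table.to_csv(OUT / f"{study_id}.csv", index=False, float_format=FLOAT_FORMAT)
    print(f"{study_id}: {len(table)} raw measurements "
          f"({table['substitutions'].nunique()} variants)")
truth.to_csv(OUT / "truth.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT)
print(f"planted archetype frequencies:\n{truth['archetype'].value_counts()}")
write_manifest(OUT / "manifest.json", "analysis/01_simulate", seed=SEED)
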