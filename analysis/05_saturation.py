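#!/usr/bin/env python
"""Has the subtype catalogue saturated at this dataset size?

Re-runs the full clustering on growing random subsets (seeded shuffles) and
tracks the number of numbered subtypes. A plateau near the planted archetype
count indicates the landscape is large enough to expose its subtype
structure; a still-rising curve would mean more data would reveal more.
"""

import sys
from pathlib import Path

import pandas as pd

from dmscape.ingest import ProfileSet
from dmscape.io import write_combined_tsv, write_manifest
from dmscape.subtypes import saturation_analysis

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
ROOT = Path(__file__).resolve().parent.parent / "results"

profiles = ProfileSet.from_frame(pd.read_csv(ROOT / "combined.tsv", sep="\t"))
table = saturation_analysis(profiles, start=1000, step=200, n_shuffles=3, seed=SEED)
means = table.groupby("size")["n_subtypes"].mean()
print("mean numbered-subtype count by subset size:")
print(means.to_string())
truth = pd.read_csv(ROOT / "sim" / "truth.tsv", sep="\t")
n_planted = (
    truth[truth["archetype"] != "permissive"].groupby("wt_aa")["archetype"].nunique().sum()
)
print(f"planted ceiling: {n_planted} non-permissive archetypes")
write_combined_tsv(table, ROOT / "saturation.tsv")
write_manifest(ROOT / "saturation.manifest.json", "analysis/05_saturation",
               inputs=[ROOT / "combined.tsv"], seed=SEED)
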