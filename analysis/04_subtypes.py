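#!/usr/bin/env python
"""Cluster positions of each amino acid into subtypes and characterize them.

Runs the permissive split + PC2-PC20 cosine clustering + hybrid tree cut,
compares the recovered subtypes with the planted archetypes (adjusted Rand
index), and writes assignments, per-subtype mean profiles, the
subtype-profile correlation matrix and the most selective subtype per
amino acid.
"""

from pathlib import Path

import pandas as pd
from sklearn.metrics import adjusted_rand_score

from dmscape.ingest import ProfileSet
from dmscape.io import write_combined_tsv, write_manifest
from dmscape.subtypes import (
    assign_subtypes,
    correlate_subtypes,
    count_numbered_subtypes,
    most_selective_subtype,
    subtype_mean_profiles,
)

ROOT = Path(__file__).resolve().parent.parent / "results"

profiles = ProfileSet.from_frame(pd.read_csv(ROOT / "combined.tsv", sep="\t"))
assignments = assign_subtypes(profiles)
labels = pd.Series(assignments["label"].to_numpy(), index=profiles.index)
summary = subtype_mean_profiles(assignments, profiles)

n_numbered = count_numbered_subtypes(labels)
print(f"{n_numbered} numbered subtypes; "
      f"{(labels.str[1:] == 'P').sum()} permissive and "
      f"{(labels.str[1:] == 'O').sum()} outlier positions")

truth = pd.read_csv(ROOT / "sim" / "truth.tsv", sep="\t").set_index(
    ["study", "gene", "position", "wt_aa"]
).loc[profiles.index]
planted = profiles.index.get_level_values("wt_aa") + ":" + truth["archetype"]
numbered = labels.str[1:].str.isdigit()
ari = adjusted_rand_score(planted[numbered.to_numpy()], labels[numbered])
print(f"adjusted Rand index vs planted archetypes (numbered only): {ari:.3f}")

corr, order = correlate_subtypes(summary[summary.index.str[1:].str.isdigit()])
selective = most_selective_subtype(summary)
print(f"most selective subtype per amino acid: "
      f"{selective.dropna().to_dict()}")

write_combined_tsv(assignments, ROOT / "assignments.tsv")
write_combined_tsv(summary.reset_index(), ROOT / "subtypes.tsv")
write_combined_tsv(corr.loc[order, order].reset_index(names="label"),
                   ROOT / "subtype_correlation.tsv")
write_manifest(ROOT / "subtypes.manifest.json", "analysis/04_subtypes",
               inputs=[ROOT / "combined.tsv"])
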