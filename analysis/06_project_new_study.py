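#!/usr/bin/env python
"""Project a brand-new study onto the stored reference landscape.

Freezes the fitted landscape + subtype catalogue into a reference bundle,
simulates a fresh study that the reference has never seen, normalizes it,
imputes its gaps from the *reference* medians, projects it through the
stored PCA/UMAP, and predicts a subtype for every position. Reports how
often fresh draws from each planted archetype land in the subtype recovered
from that archetype.
"""

import sys
from pathlib import Path

import pandas as pd

from dmscape.ingest import (
    ProfileSet,
    StudyConfig,
    filter_positions,
    process_study,
    substitution_type_medians,
)
from dmscape.io import read_combined_tsv, write_combined_tsv, write_manifest
from dmscape.landscape import fit_pca
from dmscape.project import (
    assign_subtypes_frame,
    build_reference_bundle,
    impute_with_reference,
    project_positions,
)
from dmscape.subtypes import assign_subtypes
from dmscape.synthetic import StudySpec, SyntheticSpec, generate_landscape

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
ROOT = Path(__file__).resolve().parent.parent / "results"

profiles = ProfileSet.from_frame(pd.read_csv(ROOT / "combined.tsv", sep="\t"))
model, pc_scores = fit_pca(profiles)
assignments = pd.read_csv(ROOT / "assignments.tsv", sep="\t")
# medians must come from the reference's filtered long table; rebuild it
filtered_long = []
for study_id, gene in [("study_A", "geneA"), ("study_B", "geneB"), ("study_C", "geneC")]:
    from dmscape.io import read_study_csv

    table = process_study(
        read_study_csv(ROOT / "sim" / f"{study_id}.csv"),
        StudyConfig(study_id=study_id, gene=gene),
    )
    filtered_long.append(table)
medians = substitution_type_medians(
    filter_positions(pd.concat(filtered_long, ignore_index=True))
)
bundle = build_reference_bundle(
    profiles, model, pc_scores, assignments, medians, umap_seed=SEED
)
bundle.save(ROOT / "reference")
print(f"reference bundle: {len(bundle.centroids)} subtype centroids")

fresh_spec = SyntheticSpec(
    studies=(StudySpec("fresh", "geneF", scale=1.3, n_positions=500),),
    seed=SEED + 1,
)
tables, fresh_truth = generate_landscape(fresh_spec)
fresh_table = filter_positions(
    process_study(tables["fresh"], StudyConfig(study_id="fresh", gene="geneF"))
)
fresh = impute_with_reference(fresh_table, bundle)
coords = project_positions(fresh, bundle, umap=True)
predicted = assign_subtypes_frame(fresh, bundle)
out = coords.merge(predicted, on=["study", "gene", "position", "wt_aa"])
write_combined_tsv(out, ROOT / "projected_fresh.tsv")

labels = pd.Series(assignments["label"].to_numpy(), index=profiles.index)
truth = pd.read_csv(ROOT / "sim" / "truth.tsv", sep="\t").set_index(
    ["study", "gene", "position", "wt_aa"]
).loc[profiles.index]
majority = {
    key: grp["label"].value_counts().idxmax()
    for key, grp in pd.DataFrame({
        "wt": profiles.index.get_level_values("wt_aa"),
        "archetype": truth["archetype"].to_numpy(),
        "label": labels.to_numpy(),
    }).groupby(["wt", "archetype"])
}
ft = fresh_truth.set_index(["study", "gene", "position", "wt_aa"]).loc[fresh.index]
expected = pd.Series(
    [majority.get(k) for k in zip(fresh.index.get_level_values("wt_aa"), ft["archetype"])],
    index=fresh.index,
)
pred = pd.Series(predicted["label"].to_numpy(), index=fresh.index)
mask = expected.notna() & expected.str[1:].fillna("").str.isdigit()
print(
    f"fresh positions assigned to the matching recovered subtype: "
    f"{100 * (pred[mask] == expected[mask]).mean():.1f}% of {int(mask.sum())}"
)
write_manifest(ROOT / "projected_fresh.manifest.json", "analysis/06_project_new_study",
               inputs=[ROOT / "combined.tsv", ROOT / "assignments.tsv"], seed=SEED)
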