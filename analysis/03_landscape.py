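#!/usr/bin/env python
"""Fit the mutational landscape: PCA across all profiles + 2-D UMAP.

Reports how much of the profile variance the tolerance axis (PC1) explains
and its correlation with mean normalized ER, then writes the per-position
landscape table (mean ER, PC1..PC20, UMAP coordinates) and the PCA model.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from dmscape.ingest import ProfileSet
from dmscape.io import write_combined_tsv, write_manifest
from dmscape.landscape import fit_pca, fit_umap, landscape_table, mean_er

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
ROOT = Path(__file__).resolve().parent.parent / "results"

profiles = ProfileSet.from_frame(pd.read_csv(ROOT / "combined.tsv", sep="\t"))
model, pc_scores = fit_pca(profiles)
share = model.explained_variance / model.explained_variance.sum()
r = np.corrcoef(pc_scores["PC1"], mean_er(profiles))[0, 1]
print(f"PC1 explains {100 * share[0]:.1f}% of profile variance")
print(f"corr(PC1, mean ER)^2 = {r * r:.4f} — PC1 is the overall-tolerance axis")

embedding, _ = fit_umap(profiles, seed=SEED)
write_combined_tsv(landscape_table(profiles, pc_scores, embedding),
                   ROOT / "landscape.tsv")
model.to_json(ROOT / "pca.json")
write_manifest(ROOT / "landscape.manifest.json", "analysis/03_landscape",
               inputs=[ROOT / "combined.tsv"], seed=SEED)
print(f"wrote {ROOT / 'landscape.tsv'} ({len(profiles)} positions)")
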