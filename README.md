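# dmscape

Deep mutational scanning (DMS) experiments measure the fitness effect of
every single amino acid substitution in a protein. Individually, each scan
describes one protein under one selection; combined, many scans describe how
*positions* behave in general — which ones tolerate everything, which ones
reject proline, which ones demand a hydrophobic or a charged residue.
`dmscape` is a library + CLI for building and using such combined
**mutational landscapes**:

1. **Normalize** heterogeneous studies onto a common enrichment-ratio (ER)
   scale. Raw scores are transformed to log2 ER (0 = wild-type-like,
   negative = deleterious), replicates and comparable conditions averaged,
   multi-mutant sequences collapsed onto single substitutions, and every
   study divided by the magnitude of the median of its lowest 10% of scores,
   anchoring complete loss of function (nonsense-like behavior) at −1.
2. **Combine** studies into per-position *mutational profiles* — the
   20-vector of a position's ER scores over all target amino acids —
   filtering positions with < 15 of 20 measured nonsynonymous substitutions
   and imputing the rest with substitution-type medians.
3. **Landscape**: PCA across all profiles (PC1 tracks overall mutational
   tolerance, essentially the mean ER; PC2 onwards capture the *pattern* of
   what is tolerated) and a seeded 2-D UMAP embedding.
4. **Subtypes**: per amino acid, split off permissive positions
   (all |ER| < 0.4), cluster the rest by cosine distance on PC2–PC20 with
   average linkage, and cut the dendrogram with a hybrid dynamic tree cut
   (implemented in `dmscape.treecut`). Labels are `XP` (permissive),
   `XO` (outlier) and `X1, X2, …` by decreasing frequency for amino acid X.
5. **Project** new studies onto a frozen reference landscape and predict
   their subtypes by nearest same-amino-acid centroid in PC2–PC20 space.

A synthetic-data module generates studies with *planted* archetype
structure (intolerant, not-proline, class-specific, permissive), so the
whole pipeline is verifiable end to end without downloading any published
dataset.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (seed as the optional first argument):

```bash
python analysis/01_simulate.py 1          # 3 studies, 2,000 positions
python analysis/02_normalise_combine.py   # -> results/combined.tsv
python analysis/03_landscape.py 1         # -> results/landscape.tsv
python analysis/04_subtypes.py            # -> results/assignments.tsv, subtypes.tsv
python analysis/05_saturation.py 1        # -> results/saturation.tsv
python analysis/06_project_new_study.py 1 # -> results/projected_fresh.tsv
```

Output from a run with seed 1:

```
combined landscape: 2000 positions, 97.90% of nonsynonymous entries measured
PC1 explains 62.7% of profile variance
corr(PC1, mean ER)^2 = 0.9992 — PC1 is the overall-tolerance axis
56 numbered subtypes; 361 permissive and 31 outlier positions
adjusted Rand index vs planted archetypes (numbered only): 0.907
fresh positions assigned to the matching recovered subtype: 91.9% of 405
```

Reading these numbers: 2% of entries were deleted at random and imputed
(matching the generator's missing rate); PC1 is interchangeable with mean
normalized ER, which is why subtype clustering uses PC2–PC20 only; the
clustering recovers 56 of the 60 planted per-amino-acid archetypes almost
exactly (ARI 0.91); and when a never-seen study is projected onto the frozen
reference, 92% of its positions land in the subtype recovered from their
planted archetype.

The same steps are available as CLI subcommands over files
(`dmscape simulate|normalise|combine|landscape|subtypes|saturation|project`),
each emitting a JSON run manifest with input hashes and seeds.

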