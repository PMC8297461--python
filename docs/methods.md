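# Methods

## The common enrichment-ratio scale

Studies report fitness on incompatible native scales, so each study declares
a transform in its configuration (`identity`, `log2_ratio`, `negate`, or
`affine(a, b)`) that places scores on the log2 enrichment-ratio (ER) scale:
0 for wild-type-like behavior, negative deleterious, positive advantageous.
Replicates are averaged arithmetically; a per-condition policy
(`average` / `prefer` / `drop`) decides which selection conditions
contribute, with `prefer` restricting to the preferred condition(s).

Multi-mutant sequences are collapsed after averaging: a substitution
measured directly keeps its own score; otherwise it receives the mean score
of all sequences containing it with at most `multimutant_cap` substitutions
(default 3, per-study configurable — the appropriate cap depends on how
strongly a study's variants interact). This estimator is unbiased exactly
when the partner substitutions in those sequences have zero mean effect;
the synthetic multi-mutant generator therefore pairs withheld targets with
neutral partners, so recovery checks isolate the epistasis noise term
(standard error `epistasis_sd / sqrt(n_sequences)`).

Normalization divides every score by the **magnitude** of the median of the
study's lowest 10% of nonsynonymous scores (the `ceil(0.1·n)` smallest;
synonymous scores are excluded from the pool — they sit at 0 and the tail
is meant to capture nonsense-like total loss of function). Using the
magnitude rather than the signed median keeps the sign convention intact
while mapping the deleterious tail to −1. The construction makes the output
invariant to positive rescaling of the input and equivariant in sign; a
study whose tail median is 0 has no deleterious tail and is rejected as
degenerate. Studies with fewer than 10 nonsynonymous scores are rejected.

Positions with fewer than 15 of the 20 possible nonsynonymous substitutions
(19 missense + nonsense; synonymous does not count) are dropped. Remaining
gaps are imputed with the median normalized score of the same substitution
type (A→C, A→D, …) pooled across all retained positions of all studies;
missing synonymous entries become 0 (measured synonymous scores cluster
tightly around zero). Medians are computed once over the combined filtered
dataset; adding a study invalidates them. A missing missense entry whose
type was never measured anywhere is an error; a missing nonsense score with
an empty pool is left missing, since the nonsense score is stored alongside
the profile but is not part of the clustered 20-vector. Positions covered
by several studies are kept as separate profiles keyed by study; a
wild-type disagreement with a study's declared map warns and trusts the
study.

## Landscape

PCA is fit across the whole landscape (permissive positions included) at
full rank (20 components, exact reconstruction). Loading signs are fixed so
each component's largest-magnitude element is positive, making serialized
models stable across refits. PC1 is empirically the overall-tolerance axis:
its correlation with mean normalized ER exceeds r² = 0.99 on synthetic
landscapes whose dominant variation is profile magnitude. UMAP
(`n_neighbors=15`, `min_dist=0.1`, Euclidean metric) runs on the raw
20-dimensional profiles rather than PC scores — the embedding and the PCA
are parallel views of the same matrix — with a fixed seed, which makes the
embedding deterministic and the fitted transformer reusable for
out-of-sample projection.

## Subtypes

Per amino acid: (1) positions with max |ER| < 0.4 over all 20 entries are
split off as permissive — their profile direction is mostly noise, which
matters because (2) the remaining positions are clustered by **cosine**
distance (angle only, magnitude ignored) on their PC2–PC20 scores with
average linkage, and (3) the dendrogram is cut with the hybrid dynamic tree
cut. Excluding PC1 and using cosine distance both serve the same purpose:
without them, overall tolerance dominates and pattern differences
(e.g. "rejects proline" vs "requires hydrophobic") are masked.

The tree cut (`dmscape.treecut.cutree_hybrid`) implements the Dynamic
Hybrid algorithm: branches become preliminary clusters when they satisfy
minimum size (default 20), core-scatter and gap criteria; `deep_split`
(0–4, default 0, per-amino-acid configurable) maps to
(max core scatter, min gap) fractions (0.64, 0.27), (0.73, 0.2025), … of
the dendrogram height range between the 5th-percentile merge and the cut
height (99% of the tallest merge). An assignment stage then attaches each
unlabelled point to the cluster with the smallest average dissimilarity,
provided that dissimilarity is within the cluster's diameter (largest
within-cluster dissimilarity); remaining points are outliers (id 0). Two
deterministic choices close gaps in the published description: a branch's
"core" is its members with the lowest joining heights (not an append-order
prefix), and members absorbed in a non-splitting merge keep their original
joining heights. Both make the cut invariant to input row order up to
relabelling. An optional automatic `deep_split` rule (maximize mean
silhouette) was considered and left out; the per-amino-acid mapping is
plain configuration.

Labels: permissive → `XP`, outliers → `XO`, clusters renumbered `X1…Xk` by
decreasing size with ties broken by smaller mean intra-cluster cosine
distance, then lowest member index (determinism). Subtype frequency is
size over all positions of that amino acid, so each amino acid's
frequencies sum to 1. The "most selective" subtype per amino acid defaults
to the most negative overall mean ER (most intolerant); a flag flips to the
largest mean ER reading. Subtype mean profiles are compared by Pearson
correlation with average-linkage grouping on 1 − r.

Saturation analysis re-runs the full pipeline (PCA refit on the subset,
then clustering) on growing prefixes of seeded position shuffles and counts
numbered subtypes; a plateau indicates the catalogue has stopped growing
with data size.

## Projection of new studies

A reference bundle freezes the PCA model, the UMAP seed/parameters plus its
training matrix (the transformer is re-fit deterministically on load — no
binary serialization), per-subtype centroids (mean member PC2–PC20 vector)
with an assignment radius, the imputation medians and the permissive
threshold. New studies are normalized by the standard pipeline, imputed
from the *reference* medians (the reference's substitution statistics are
better estimated than a single new study's), and classified: permissive
rule first, then nearest same-amino-acid centroid by cosine distance,
demoted to `XO` beyond the radius. The default radius is the farthest
member's distance (100th percentile): a lower percentile (it is
configurable) makes outlier calls stricter but necessarily re-labels that
fraction of the reference's own members as outliers, which breaks the
expectation that re-projecting the reference reproduces its own catalogue.
An amino acid with no numbered subtype in the bundle yields `XO` for
non-permissive queries; an amino acid entirely absent from the reference is
an error.

## Synthetic data: what it emulates, and what it does not

Each position draws an archetype for its wild-type amino acid:
`intolerant` (all −1), `not-proline` (0 except P = −1), a class archetype
(`hydrophobic-only` or `polar-only`: 0 within the wild type's
physicochemical class, −1 outside), or `permissive` (all 0), with default
weights 0.30/0.25/0.25/0.20 and per-entry Gaussian noise (sd 0.1 — archetype
separation ~1 is an order of magnitude above the noise). The permissive
archetype clips its entries to ±0.2, half the permissive threshold, so
planted permissive positions remain permissive through replicate noise and
normalization. Nonsense scores are −1. Studies apply a positive
multiplicative scale (defaults 1.0/2.5/0.7 across three studies of 600–700
positions), three replicates with Gaussian jitter (sd 0.1 × scale), and 2%
missing-completely-at-random entry deletion — chosen to reproduce the
~98% measured fraction typical of curated combined datasets. Multi-mutant
sequences score as the sum of member effects plus Gaussian epistasis noise.

The generator does **not** emulate: read-count sampling noise or selection
dynamics, non-random (structured) missingness, between-replicate
systematic drift, correlated noise along the sequence, or real biophysical
archetype geometry. Passing tests therefore demonstrate that the pipeline's
*operations* are correct and that its clustering recovers structure of the
planted kind at realistic noise/missingness levels — not that any
particular real protein's subtypes are recoverable.

Imputation interacts with the archetype mixture in one noteworthy way: a
substitution type that most positions reject (e.g. anything → proline) has
a strongly negative pooled median, so a planted-permissive position with
that entry missing is legitimately completed to a non-permissive profile.
About 15% of planted-permissive positions are affected at the default
missing rate; the permissive *rule* (max |ER| < 0.4 on the completed
profile) remains exact by construction.

## Numerical and scale choices

- Bottom-decile median: the `ceil(0.1·n)` smallest values, standard
  even-count median; division by its absolute value.
- Cosine distance on exactly-zero PC2–PC20 rows is undefined; such rows
  (possible only for profiles identical to the landscape mean along those
  axes) get distance 1 to everything rather than poisoning the matrix.
- Equal-size subtype ties, PCA signs and saturation shuffles are all
  deterministic; every stochastic step (generator, UMAP, shuffles) takes an
  explicit seed, and CLI runs record seeds and input hashes in a manifest.
- Analysis and acceptance runs use a 2,000-position landscape (three
  studies), 500-position fresh studies, and saturation from 1,000 positions
  in steps of 200–500 with 2–3 shuffles — sizes at which the planted
  structure is comfortably above the minimum cluster size (about 25–30
  members per archetype per amino acid against the default minimum of 20)
  while the full suite stays fast.

## Known limitations

- The tree cut follows the published Dynamic Hybrid description plus the
  two documented determinism choices; borderline branches close to the
  core-scatter/gap thresholds may be cut differently than by other
  implementations of the same algorithm.
- `deep_split` defaults to 0 for every amino acid; real landscapes may need
  per-amino-acid tuning (the mapping is a plain configuration field).
- UMAP's `transform` places genuinely novel profile patterns near their
  nearest training structure; the subtype prediction guards against this
  with the centroid radius, the embedding does not.
- Projection assumes the new study normalizes onto the same ER scale; a
  study whose deleterious tail is not loss-of-function-like will land
  systematically off-axis.
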