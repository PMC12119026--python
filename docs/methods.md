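# Methods

`cortexdev` re-implements, as a tested library, the comparative
single-nucleus transcriptomic analysis of a developing sensory cortical
area sampled at two postnatal ages and under two sensory-deprivation
conditions. Every analysis stage can be exercised on synthetic data with
planted ground truth, so recovery and calibration are measurable rather
than assumed. This note documents the models, the defaults and why they
are what they are, and what the synthetic benchmarks do and do not show.

## Synthetic data model

Counts for cell *c* and gene *g* are negative binomial (Gamma–Poisson):

    x_cg ~ NB(mean = mu_cg, inverse dispersion = theta_g)
    mu_cg = b_g * 2^(sum of applicable planted log2 effects) * s_c

with `var = mu + mu^2/theta`. Defaults: `theta = 0.5` for all genes
(strongly overdispersed, UMI-like nuclear data), log-normal size factors
`s_c ~ LogN(0, 0.35)`, and baselines `b_g` chosen so a typical cell has
~2,500–3,000 total counts. Zero inflation is not modeled; for UMI-type
counts the NB zero mass is adequate and keeps the planted truth tractable.

The taxonomy is 2 classes / 12 subclasses / 45 types. Per-type cell counts
follow a deterministic log spread spanning one order of magnitude by
default (`frequency_spread = 10`), because real type frequencies span
orders of magnitude and a uniform composition makes frequency-concordance
correlations degenerate. Planted gene programs:

| program | default size | effect (log2) | applies |
|---|---|---|---|
| subclass-specific temporal (Q1) | 5/subclass | ±2 at the older age, one subclass | temporal + subclass axes |
| global temporal (Q2) | 40 | ±2 at the older age, all subclasses | temporal axis |
| housekeeping (Q3) | 100 | none, high baseline | neither |
| subclass markers (Q4) | 20/subclass | +2 in one subclass | subclass axis |
| type markers | 8/type (30/type in the continuum subclass) | +2 in one type | within-subclass |
| immediate-early genes | 10 | +2 in the brief-deprivation condition | condition contrast |

Two structural constraints make the planted truth self-consistent:

* **Library balance.** Temporally down-regulated genes start from a
  `2^|e|`-scaled baseline (high early, low late, like developmental genes
  switched off during maturation). Without this, `mean(2^e) > 1` for
  balanced ± effects, total counts differ between ages, and library-size
  normalization induces a systematic shift in every "static" gene — the
  planted Q3/Q4 truth would be false in normalized space.
* **Marker multiplicity.** Types carry at least 8 markers so mean marker
  scores are not dominated by a single gene's sampling noise.

The continuum subclass draws a latent coordinate `u in [0,1]` from a
mixture of three sharp Beta components; triangular hat memberships
`w_t(u)` interpolate the three type-marker effect profiles, and the type
label is `argmax w`. The compositional shift between ages is planted in
the mixture weights: (0.50, 0.20, 0.30) at the younger age versus
(0.25, 0.40, 0.35) later — type A halves, B doubles, C is stable.

Artifacts: doublets are sums of two random cells' draws (expected library
≈ 2× a singlet); low-quality cells are binomially thinned to a target
total drawn uniformly in [50, 400], below the 500-count retention floor;
damaged high-mitochondrial cells blend 50% toward the baseline profile
(partial identity loss) with mitochondrial means boosted to a 20–40%
fraction and drawn Poisson, since a bulk fraction is not per-gene bursty.
The doublet-score column emulates an imperfect external caller
(Beta(6,3) for doublets vs Beta(3,6) for singlets); the pipeline treats it
as an input, and `qc.naive_doublet_score` provides a plumbing fallback
(correlation to synthetic doublet centroids) for data without one.

## Quality control

Cells are retained iff `n_genes < 7,000` and `500 < n_counts < 40,000`
(strict inequalities); genes detected in fewer than 100 cells are removed
(configurable; small fixtures use proportionally smaller values). Each
cell is rescaled to 10,000 counts and log1p-transformed (natural log;
recorded in the output metadata). Clustering is HVG selection by
mean-dispersion binning (n=2,000), z-scoring, PCA (40 components), a
15-nearest-neighbor graph, and Leiden at resolution 1.0, all seeded.
Clusters whose mean mitochondrial fraction is ≥ 0.2 are removed whole. An
optional per-cell mitochondrial cap exists but is off by default; the
cluster-level rule is the default pathway. Mapping-based purification
removes clusters that map diffusely to a reference (operationalized as:
top mapped label share < 0.5 AND mean top probability < 0.5 — a monotone,
auditable rule) and, within retained clusters, cells whose mapped label
accounts for < 2% of the cluster.

## Differential expression and quadrants

All tests are two-sided Wilcoxon rank-sum on log-normalized expression.
With both groups ≤ 8 cells, the p-value is an exact rank-split enumeration
(mid-ranks, permutation two-sided definition); otherwise the tie-corrected
normal approximation with continuity correction. Candidates are genes
expressed (nonzero) in > 40% of cells in at least one group (20% for the
brief-deprivation contrast and type-marker selection). BH FDR is applied
within one contrast's candidates — each (subclass, contrast) is its own
family. Fold changes are ratios of group means of de-logged normalized
expression with pseudocount 1e-9, reported as log2; this matches the
normalization pipeline and keeps FC a ratio of mean normalized counts.

The SV score is the capped (cap = 2, log2 scale, matching plotted axes)
maximum one-vs-rest |log2FC| over subclasses at either age; absolute
values are used, noting markers are conventionally up-regulated. The tDE
score is the capped maximum per-subclass |log2FC| between ages. At
threshold `t = log2(2)` the (SV, tDE) plane partitions into Q1 (specific
temporal), Q2 (global temporal), Q3 (static non-specific), Q4 (static
identity); the partition is verified to be robust over thresholds 1.5–2.5.

Category enrichment per quadrant uses two-sided Fisher's exact tests on
2×2 tables over the scored-gene universe (not an external all-gene
background), sample odds ratios with a 0.5 Haldane correction only when
exactly one cell is zero (flagged), and Bonferroni adjustment over all
quadrant × category tests; calls are enriched/depleted only at adjusted
p ≤ 0.05. Cross-region overlap of temporal gene lists uses the
hypergeometric upper tail P(X ≥ k) with the universe set to all genes
regulated in any subclass, Bonferroni-multiplied by the number of
subclasses tested. UpSet-style summaries count each significant gene in
exactly one exclusive subclass combination; combinations under 4 genes are
suppressed from display but retained in totals.

## Label transfer

A multiclass XGBoost ensemble (`multi:softprob`, mlogloss, eta 0.2,
max depth 6, subsample 0.6) is trained on the reference labels over the
intersection of reference/test HVGs (reference gene order). Per cluster,
70% of cells (capped at 1,000) are sampled for training; clusters with
fewer than 100 sampled cells are bootstrapped to 100; all unsampled cells
are held out for validation. Boosting runs up to 200 rounds with early
stopping (10 rounds) on a 10% tune split of the training cells — the round
count is not stated by the protocol, so it is fixed here and recorded in
the manifest. A test cell is assigned `argmax p` only if
`max p > 1.2/r` strictly (r = number of reference labels); otherwise
Unassigned. Raising the rejection factor can only shrink the assigned set.
Determinism holds for a fixed seed and thread count (single-threaded by
default).

Frequency concordance normalizes label frequencies within the stated level
and reports linear Pearson r (log10 frequencies optionally, since
frequencies span orders of magnitude and are plotted on log axes). A type
is flagged as off-diagonal when |log2(f_a/f_b)| > log2(1.5); the planted
shift is a 2× deviation, so the 1.5× rule flags it with margin while
multinomial noise at benchmark sample sizes stays well inside it. The
over-clustering diagnostic reruns the train/validate protocol per
clustering resolution and flags the smallest resolution whose mean
per-cluster held-out error exceeds 10%.

## Continuum (L2/3-style) analysis

Type markers are one-vs-rest up-regulated genes (FC > 1.5, FDR < 0.05 per
type, expressed in > 20% of the type's cells — all genes passing the
gates, not a fixed top-k); their union is the PCA feature set, selected
once on the reference condition and held fixed across conditions. PCA is
centered but not re-scaled by default (`scale` flag available, recorded);
component signs are fixed by making the largest-magnitude loading
positive. Eigenvector correspondence between conditions is the |dot
product| matrix of loadings (loadings are orthonormal, so this equals the
loading correlation up to centering; the Pearson variant is also
available), with 1:1 correspondence declared when the optimal assignment
is the diagonal. Per-cell type scores are arithmetic means of marker
expression. Score distributions are compared between conditions with
two-sample two-sided KS tests; `pc1_profile` reports raw p plus Bonferroni
adjustment over all type × condition-pair tests in the call, following the
same multiple-testing convention as the overlap tests. Profile curves are
sliding-window means (default window 10% of cells) of scores over cells
ordered by PC1 — diagnostics only; the KS tests carry the inference.

## Benchmarks and problem sizes

`cortexdev.benchmarks` builds the study-condition fixtures and measures:

* **Classifier validation**: 12 subclasses × 1,000 cells, 2,000 genes, 50
  markers/subclass at log2FC 2, theta 0.5; full split/upsample/train
  protocol; reports overall held-out accuracy.
* **Quadrant recovery**: ~1,000 cells/subclass/condition, 1,200 genes,
  no continuum subclass — its type markers sit exactly at the Q4/Q3
  boundary at subclass resolution (a marker present in ~1/3 of a subclass
  has one-vs-rest log2FC ≈ 1), which would measure an intentionally
  ambiguous planting instead of recovery; per-quadrant precision/recall in
  each class context plus the 1.5–2.5 threshold sweep.
* **Shift specificity**: 20 repeats, 333 cells/type/condition with uniform
  stable-type sizes — the controlled experiment for "only the continuum
  subclass shifts"; rare stable types would reintroduce legitimate
  FDR-level false marker discoveries of temporal genes that confound the
  planted null. Judged on the family-wise Bonferroni KS screen.
* **Eigenvector correspondence**: two independent fixtures of the
  continuum subclass (400 cells/type), markers selected on the first.
* **Null calibration**: 20 null fixtures × 2,000 genes for the DE
  false-positive rate; 100 KS repeats at n=500 for rejection rate.

These sizes are desk-scale choices that keep every benchmark reproducible
in minutes on one CPU while leaving comfortable statistical margins.

## What passing benchmarks does not show

The generator emulates the statistical skeleton of the real data, not the
data: no ambient RNA, no batch or replicate structure beyond random
assignment, no read- or UMI-level noise, independent genes given the
planted effects (no co-expression modules), a single dispersion for all
genes, and a one-dimensional continuum. Passing recovery benchmarks shows
the machinery is correct and calibrated under its stated model; it does
not certify performance on data violating these assumptions. Headline
counts from the real study (numbers of nuclei, types, regulated genes,
quadrant percentages) depend on the real data and are deliberately not
reproduction targets; the reproduced quantity is the protocol-level
classifier validation bound.

## Degenerate inputs and numerical conventions

Empty DE groups, missing timepoints, constant frequency vectors, empty
marker sets, zero-count cells, and r < 2 label vocabularies raise
`ValueError` rather than returning silent defaults. Zero-margin Fisher
tables return an infinite/zero OR sentinel with the exact p still
computed. Missing feature genes at prediction/PCA time are zero-filled
with a logged warning, since cross-dataset gene panels differ. All
randomness flows from `numpy.random.default_rng` seeded per run; no
global RNG state is touched.
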