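# cortexdev

Comparative single-nucleus transcriptomics of developing sensory cortex,
re-implemented as a tested, reusable Python pipeline. The package is for
computational biologists who want to run — or stress-test on data with a
known answer — the analysis stack used to ask how cortical neuron types
mature between two postnatal ages and how sensory deprivation perturbs
them: quality control and cluster purification, temporal/subclass
differential-expression "quadrant" scoring, gene-category enrichment,
classifier-based cell-type label transfer, a marker-PCA continuum analysis
of L2/3 pyramidal types, and cross-region overlap statistics.

Every stage runs on synthetic count matrices with planted ground truth
(negative-binomial counts over a 2-class / 12-subclass / 45-type taxonomy,
with planted temporal programs, markers, a three-type continuum with a
compositional shift, and QC artifacts), so recovery, precision/recall, and
statistical calibration are measured, not assumed.

## The statistics at the core

For each gene *g* the analysis computes two capped scores from Wilcoxon
rank-sum contrasts on log-normalized expression:

* **SV score** — subclass variability: `min(2, max over subclasses s and
  ages t of |log2 FC_one-vs-rest(g; s, t)|)`
* **tDE score** — temporal regulation: `min(2, max over s of
  |log2 FC_age(g; s)|)`

At a fold threshold of 2 (log2 threshold 1) the (SV, tDE) plane partitions
genes into Q1 (subclass-specific temporal program), Q2 (global temporal
program), Q3 (static housekeeping), Q4 (static identity). Category
enrichment per quadrant is Fisher's exact test with Bonferroni adjustment;
overlap of temporally regulated gene lists between regions is the
hypergeometric upper tail `P(X >= k)` with `X ~ Hypergeom(N, K, n)`.

Label transfer trains a multiclass XGBoost ensemble (eta 0.2, depth 6,
subsample 0.6) on 70% of each reference cluster (capped at 1,000,
bootstrapped up to 100 for small clusters), validates on the held-out
cells, and assigns a test cell to `argmax p` only when
`max p > 1.2/r`, else "Unassigned". The L2/3 continuum analysis does PCA
per condition on the union of type markers (FC > 1.5, FDR < 0.05,
expressed in > 20% of the type), compares eigenvectors across conditions
by loading dot products, and tests marker-score distributions between
conditions with two-sample KS statistics.

See `docs/methods.md` for the full model, defaults, and caveats.

## Worked example

Run the end-to-end pipeline on a clean synthetic cohort (60 cells/type,
1,000 genes, four conditions: young control, older control, 10-day and
1-day deprivation):

```python
from cortexdev.pipeline import run_pipeline, report

cfg = {"seed": 7,
       "simulate": {"cells_per_type": 60, "n_genes": 1000,
                    "doublet_rate": 0.0, "lowq_rate": 0.0,
                    "himito_rate": 0.0, "frequency_spread": 1.0},
       "qc": {"n_hvg": 500, "min_cells_per_gene": 10},
       "overlap": {"region2_seed": 99}}
run_pipeline(cfg, "out/demo")
print(report("out/demo"))
```

which prints (abridged):

```
"mapping_accuracy": 0.97539975399754,
"frequency_concordance": {"P12": 0.963, "P22_AWD": 0.996, "P22_RWD": 0.988},
"quadrant_sizes": {"Q1": 60, "Q2": 80, "Q3": 1263, "Q4": 400},
"enrichment_calls": {"depleted": 5, "enriched": 5, "neither": 6},
"l23_min_ks_p_adj": 5.08e-05,
"n_scored_genes": 1803
```

Reading the numbers: the held-out validation accuracy of the subclass
classifier is 97.5%; relative type frequencies in each perturbed/younger
condition correlate with the reference at r = 0.96–0.996; the quadrant
table recovers the planted programs (60 subclass-specific temporal genes,
80 global temporal genes across the two class contexts, 400 static
markers, the rest static/non-specific); the synthetic housekeeping and
adhesion/channel categories produce 10 significant enrichment/depletion
calls; and the continuum subclass — the only one whose type composition
was shifted between ages — yields the one significant KS comparison
(adjusted p ≈ 5e-5). The same stages are available as a CLI
(`cortexdev simulate|qc|quadrants|map|l23|overlap|run|report`), and every
run writes a JSON manifest with all thresholds, seeds, counts, and output
hashes.

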