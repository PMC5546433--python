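# cdksig

A tested, reusable pipeline for deriving a **composite transcriptional
response signature for CDK4/6 inhibitors** from multi-condition
differential expression, testing that signature for enrichment of
viability-essential genes, and stratifying a tumor cohort by signature
expression for recurrence-free-survival analysis.

CDK4/6 inhibitors (palbociclib "PD", abemaciclib "LY") arrest the cell
cycle by preventing phosphorylation of the retinoblastoma protein (RB);
their transcriptional consequence is repression of the E2F-regulated
cell-cycle program — but only in RB-proficient cells, and partly entangled
with agent-specific off-target effects.  The pipeline isolates the shared,
RB-dependent response: a gene enters the composite signature only if it is
consistently up- or down-regulated past a log2 fold-change threshold, with
a significant t-test, in *every* RB-proficient drug-vs-vehicle comparison.
The package is aimed at computational biologists who want the complete
derivation — normalization, per-contrast statistics, consistency
filtering, enrichment and survival endpoints — as composable, validated
Python functions, with a synthetic-data generator providing planted ground
truth in place of proprietary microarray and cohort data.

## The method

For each contrast (treated vs vehicle within one model and context), on
quantile-normalized log2 intensities:

- log2 fold change: `logFC(g) = mean(treated) − mean(control)`;
- two-tailed Student's homoscedastic (pooled-variance) t-test,
  `df = n1 + n2 − 2`.

The composite signature over contrasts `c = 1..K` (all RB-proficient):

```
repressed = { g : logFC_c(g) < −τ  and  p_c(g) ≤ α   for all c }
induced   = { g : logFC_c(g) > +τ  and  p_c(g) ≤ α   for all c }
```

with `τ = 0.5` (log2) and `α = 0.05` by default; a 1.5-fold preset
(`τ = log2 1.5 ≈ 0.585`) is available.  No multiple-testing correction is
applied; cross-condition consistency is the multiplicity control.

Enrichment of essential genes uses a two-sided chi-square test of equal
proportions (R's `prop.test`, Yates correction on by default) comparing
the essential fraction inside the signature to the whole gene universe,
where a gene is "essential" when its viability-screen p-values are < 0.05
in every tested cell line.

Prognostic stratification scores each tumor case by the mean log2
expression of the signature genes, dichotomizes cases at the median score
or at the root branch of an unsupervised hierarchical clustering
(z-scored genes, Euclidean distance, complete linkage), and compares
groups with the Kaplan-Meier estimator, the log-rank test, and a
univariate Cox proportional-hazards model (Efron ties).

## Worked example

```python
from cdksig.cli import run_pipeline

report = run_pipeline(seed=1)
print(report["signature"]["n_repressed"], report["signature"]["n_induced"])
```

With the default synthetic study (10,000 genes; 78 planted repressed and
4 planted induced genes at one log2 unit; Gaussian noise σ = 0.25; six
RB-proficient contrasts at 3 replicates/arm), seed 1 prints:

```
repressed: 59
induced: 2
essential in signature: 15 of 61 vs 495 of 10000 (chi2=44.60, p=2.411e-11)
logrank chi2=138.1 p=6.982e-32 ; Cox HR=2.59 (Wald p=6.334e-30)
```

Reading this: 59 of the 78 planted repressed genes survive the
six-contrast consistency-and-significance intersection (requiring
p ≤ 0.05 in all six 3-vs-3 t-tests caps per-gene recovery near
0.95⁶ ≈ 0.73, with essentially no false positives); the recovered
signature is strongly enriched for simulated screen-essential genes
(15/61 vs the ~5% background); and dendrogram stratification of a
simulated 900-case cohort with planted hazard ratio 2.5 recovers
HR ≈ 2.59 with an overwhelming log-rank separation.

The same stages are available as a CLI:

```sh
cdksig simulate-expression --out-dir sim --seed 1
cdksig diffexp --matrix sim/expression.tsv --annotation sim/annotation.tsv --out-dir de
cdksig signature --diffexp-dir de --out-dir sig          # add --fold 1.5 for the fold preset
cdksig run-all --out-dir out --seed 1                     # end-to-end JSON report
```

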