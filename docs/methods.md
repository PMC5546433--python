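# Methods

This note documents the statistical model behind `cdksig`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions at the edges.

## Differential expression

All expression values are log2 intensities.  Quantile normalization maps
every sample onto the mean empirical distribution: each output column,
sorted, equals the across-sample mean of the order statistics at each
rank.  Values tied within a column receive the mean of the reference
values over their tied ranks — the standard convention, and the one that
makes the operation idempotent.  Normalization is computed once per input
matrix (all samples of an experiment together), before any contrast.

Each contrast compares treated to vehicle samples of one cell model in
one context (cell line or xenograft), each arm with at least two
replicates.  Per gene it reports the difference of group means (the log2
fold change) and a two-tailed pooled-variance Student t statistic with
`n1 + n2 − 2` degrees of freedom.  Fold-change thresholds are on the log2
scale throughout: the default ±0.5 corresponds to ≈1.41-fold, and a
1.5-fold preset (log2 1.5 ≈ 0.585) is exposed for the stricter reading of
"changed by greater than 1.5-fold"; the looser ±0.5 is the default
because it is the operative recipe of the derivation being reproduced.

No multiple-testing correction is applied anywhere.  The derivation works
on raw p ≤ α per contrast; the conjunction of the threshold and
significance filters across all conditions is what controls false
discoveries (empirically, the false-discovery proportion of the composite
signature on planted-truth simulations is indistinguishable from zero).

Zero pooled variance — reachable only with noiseless synthetic data — is
handled without crashing: t = 0, p = 1 when the group means agree, and
p = 0 plus a per-gene degenerate flag when they differ.

## Composite signature

A gene is in the repressed (induced) set iff, in every RB-proficient
drug-vs-vehicle contrast supplied, its logFC is strictly below −τ
(above +τ) *and* its t-test p is ≤ α.  Strict inequality on the
threshold means a gene sitting exactly at ±τ is excluded.  "All
conditions" defaults to every RB-proficient contrast in the run, pooling
cell-line and xenograft contexts; including an RB-deficient contrast
requires an explicit override, and the contrast set is always recorded in
the signature's provenance.  The derivation is deterministic and
invariant to contrast order.

A consequence worth stating explicitly: with triplicate arms and
per-sample noise σ = 0.25 on a one-log2-unit effect, a single 3-vs-3
pooled t-test has power ≈ 0.95 at α = 0.05, so requiring significance in
all six default contrasts caps per-gene recovery probability near
0.95⁶ ≈ 0.73.  The intersection design buys its near-zero false-discovery
proportion with sensitivity; the recovered signature is a conservative
subset of the planted program, not an exhaustive census.  The recovery
tests freeze this empirically confirmed operating point (mean sensitivity
in [0.6, 0.85], FDP ≤ 0.02 over seeds).

## Essential-gene enrichment

A gene is labeled essential when its screen p-values are < α in the
tested cell lines.  The default rule requires every non-missing cell line
("broad inhibition of viability"); `any` and `at_least_k` are available
because the phrase is ambiguous.  Genes with no observed p-value at all
are removed from both the essential set and the evaluable universe and
reported.

The enrichment statistic is the chi-square test of equal proportions on
the 2×2 table (essential vs not, signature vs universe) — numerically
identical to R's `prop.test`, with the Yates continuity correction on by
default (the common default of that environment) and the uncorrected
statistic available by flag.  The uncorrected statistic equals the
squared two-proportion z statistic exactly.  The default background is
the *entire* gene universe including the signature genes; an exclusive
background (universe minus signature) is available.

Two numerical caveats, both verified in the test suite rather than
asserted away.  First, the asymptotic chi-square p and the exact Fisher p
rank tables almost identically but can differ several-fold in the far
tails, where both are tiny — an inherent property of asymptotic
approximations, so exact-test agreement is checked as rank agreement, not
pointwise.  Second, the chi-square's validity condition (expected cell
counts ≥ 5) fails for a small signature against a rare essential
background (e.g. 82 genes at 5%: expected count ≈ 4), where discreteness
distorts the size of the test; null-calibration checks therefore use
margins that satisfy the condition (500 of 10,000 at 5%), where the
uncorrected test's type-I error is measured at ≈ 0.05 and the Yates test
is, by design, conservative.

## Prognostic stratification and survival

Cases are scored by the unweighted mean log2 expression of the signature
genes present in the cohort matrix (absent genes dropped with a warning).
Two dichotomizers are provided, mirroring the two used in practice:

- **median split**: high = score > median; ties at the median go to
  "low" (documented convention, tested);
- **dendrogram branch**: agglomerative hierarchical clustering of cases
  on the signature genes — per-gene z-scoring, Euclidean distance,
  complete linkage by default, all configurable and recorded — cut at
  the root into exactly two branches, with the higher-mean-score branch
  labeled "high" regardless of tree orientation.

Survival comparison uses the Kaplan-Meier product-limit estimator with
right censoring (exact equality with the empirical survival function when
nothing is censored), the two-group log-rank test, and a univariate Cox
proportional-hazards fit on the high-vs-low indicator with Efron tie
handling (Breslow via flag, using an internal Newton solver since the
Efron fitter's library does not expose Breslow).  The headline p-value of
a comparison is the log-rank p; the Cox Wald p is reported alongside.
For a single binary covariate the Cox score test *is* the log-rank test,
and the score p is reported through that identity (exact when event times
are untied).  Monotone likelihood — all events in one group before any in
the other — is flagged as non-convergence rather than reported as a
finite estimate.

## Synthetic data: what it emulates, and what it does not

The expression generator plants three disjoint programs in a
`baseline(g) + model_offset + effect + N(0, σ²)` model on the log2 scale:

- an **on-target repressed program** (default 78 genes at −1 log2 unit)
  and a small **induced program** (4 genes at +1), active only in
  RB-proficient treated samples — the RB/E2F axis;
- an **off-target program** (30 genes at −1), responding to abemaciclib
  at doses ≥ 250 nM in every model regardless of RB status — the
  agent-specific, RB-independent activity that the cross-agent
  consistency filter must exclude.

The default condition grid mirrors the emulated study: MCF7 and T47D
(RB-proficient cell lines) and MB468 (RB-deficient) under palbociclib
1 µM and abemaciclib 250 nM (plus 1 µM for MB468), and MB231 xenografts
with intact or CRISPR-deleted RB under both agents at high dose — six
RB-proficient drug-vs-vehicle contrasts, five RB-deficient ones, vehicle
arms everywhere, three replicates per arm.  Noise is Gaussian and
homoscedastic across genes, the minimal model consistent with a
homoscedastic t-test; probe effects, batch structure, intensity-dependent
variance and other microarray artifacts are deliberately not simulated,
so passing tests demonstrate correctness of the statistical machinery on
its stated model, not robustness to real-array pathology.  Within one
model all contrasts share the vehicle arm, so their noise is positively
correlated — as in the real design — which is why single-model
intersections are weaker null filters than cross-model ones.

The essentiality generator draws each gene essential with probability
0.25 (signature genes) or 0.05 (background), then gives essential genes
per-line p ~ U(0, 0.05) and others p ~ U(0.05, 1); the all-lines labeling
rule recovers the planted set exactly by construction, and the planted
fractions reproduce a ~20-of-80 essential count in the signature.

The survival generator splits cases evenly into two latent groups,
shifts the signature genes by +2 (log2, against per-gene noise σ = 1) in
the high-expression group, and draws exponential recurrence times with
baseline hazard 0.01/month against 0.025/month (hazard ratio 2.5) in the
high group — high signature expression marks the proliferative,
worse-prognosis subtype.  Censoring is independent Uniform(0, c), with c
calibrated by bisection so the realized censored fraction approximates
the requested one (default 0.3).  The default cohort is 900 cases with
500 genes, large enough to exercise clustering at realistic
dimensionality.  All generators are bit-reproducible given a seed.

## Problem sizes

Simulation-backed checks use: 10,000-gene experiments over 50–100 seeds
for signature recovery; 900-case cohorts over 50–100 seeds for
prognostic power and hazard-ratio recovery; and 2,000 replicates for each
null-calibration rate.  These sizes put Monte-Carlo standard errors well
below the asserted bands while keeping a full run to a few minutes on one
CPU.

## Known limitations

- Gene identifiers are opaque strings; no aliasing or ID conversion.
- The enrichment p-value is asymptotic; for tiny signatures or very rare
  essential backgrounds an exact test would be preferable.
- The survival model is exponential with a single binary covariate; no
  multivariable adjustment, proportional-hazards diagnostics, or
  competing risks.
- The consistency-intersection signature trades sensitivity for purity,
  as quantified above; a meta-analytic combination of contrasts would
  have different operating characteristics and is out of scope.
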