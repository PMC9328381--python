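# Methods

This note documents the models, parameters and design choices behind
`mtxresponse`: what the synthetic cohort generator emulates, how each analysis
stage is defined, and where the genuinely open choices were resolved.

## Study design being emulated

The pipeline targets a paired-timepoint treatment-response design in
rheumatoid arthritis: whole-blood expression measured at pretreatment and 4
weeks after starting methotrexate, with the outcome — EULAR good response vs
nonresponse — determined from DAS28-CRP at baseline and month 6. The default
generator settings mirror that design: 42 good responders vs 43 nonresponders,
two samples per patient, and ~22,771 analysis-ready probes. Cohort size is a
parameter, not a constant, since published group totals in this literature are
not always internally consistent.

## Synthetic cohort generator

### Clinical covariates

Covariates are drawn per response group. Sex, ACPA positivity and smoking are
categorical draws with group-specific proportions (good: 76% female, 64%
ACPA+, never/past/current = 23/11/8 out of 42; nonresponders: 77%, 58%,
16/17/10 out of 43). Age at onset is normal (59 ± 15 vs 55 ± 14 years,
truncated to [18, 95]); HAQ is normal around the group median with an
IQR-matched SD, truncated to [0, 3].

Disease activity is generated top-down. A patient's baseline DAS28-CRP target
is drawn from the group's truncated normal (4.8 ± 1.0 good, 4.0 ± 1.3
nonresponders; the location is recalibrated so the *truncated* mean equals the
target). The variable part of the score (target − 0.96) is then split across
the four components with Dirichlet shares (concentration 60) centered on the
group's component medians — tender 8/6, swollen 5/3, VAS 44/32 mm, CRP on the
natural-log scale (ln CRP ≈ 2.2 ± 1 good, 1.7 ± 1 nonresponders, i.e. medians
≈ 9 and 5.5 mg/liter) — and inverted through the DAS28-CRP formula. Joint
counts are rounded and clipped to [0, 28]; VAS and then CRP absorb the
rounding residual, so the score recomputed from the emitted components equals
the drawn target almost exactly and the group means are recovered to within
a few hundredths at large n.

Two remarks on these choices. First, a published summary of "CRP 2.2 ± 1
mg/liter" cannot be a linear-scale mg/liter summary for an active-RA cohort
whose DAS28 averages 4.8; we read it as a log-scale summary, and the
natural-log reading (median ≈ 9 mg/liter) is the one consistent with both
typical RA CRP values and the component-level DAS28 arithmetic. Second,
generating components conditional on the score (rather than independently)
is what makes the DAS28 group means exactly recoverable while keeping every
component within its legal range; the cost is that component medians are
matched only approximately through the share weights.

The month-6 score is baseline minus an improvement drawn from its conditional
distribution given the patient's group: good responders require improvement
> 1.2 with a month-6 score ≤ 3.2 (improvement ~ N(2.3, 0.7) truncated to that
region), nonresponders realize EULAR "none" via improvement ≤ 0.6
(N(0.1, 0.5) truncated). Sampling the improvement conditionally — instead of
rejecting whole patients — keeps the baseline covariate distributions unbiased,
and means moderate responders never enter the emitted cohort, mirroring a
two-group design. Month-3 re-measurements of the time-varying covariates
(HAQ, joint counts, CRP, VAS) interpolate halfway to the month-6 score with
noise, supporting the month-3 clinical feature set.

DAS28-CRP uses the standard formula 0.56·√TJC28 + 0.28·√SJC28 + 0.36·ln(CRP+1)
+ 0.014·VAS + 0.96, and EULAR categories use the classic 1.2/0.6 improvement
and 3.2/5.1 level thresholds. Both are isolated behind single functions
(`compute_das28_crp`, `eular_category`) so CRP-specific threshold variants can
be swapped in; whether the emulated study used adjusted cutpoints is unknown,
so the classic grid is the default.

### Expression

Log2-scale intensities follow a latent-factor model: per-gene baseline mean
~ N(7.5, 1.5) (floored at 6), plus module factors, plus a per-sample array
offset ~ N(0, 0.15) (removed by quantile normalization), plus i.i.d. Gaussian
noise with SD 0.5 — a typical residual scale for whole-blood arrays. Genes of
a planted module load on a shared standard-normal factor per timepoint with
loading σ·√(ρ/(1−ρ)), which makes the expected within-module Pearson
correlation exactly ρ (default 0.6). Factors of nonresponder-restricted
modules are zeroed in good-responder samples: those genes are pure noise in
the good group, modular in nonresponders — the structure the consensus
comparison is designed to detect. One percent of probes are simulated as
unexpressed (baseline ≈ 3, below the detection floor of 5) so QC has real work.

The longitudinal signal: `n_signal_genes` (default 50) non-module genes
receive, in nonresponders only, a week-4 mean shift equal to `signal_effect`
standard deviations of the week4 − pretreatment difference (that SD is
√(2(σ² + offset²)) for a background gene). `signal_effect` is therefore a
standardized effect size on the delta scale; the default of 1.0 yields a
strongly but not trivially learnable signal at n = 85 (nested-CV AUC ~0.9),
and 0 gives an exact null.

What the generator does **not** emulate: probe-level array artifacts
(bead-level variance, detection p-values), batch effects, correlated
module factors across timepoints, non-Gaussian expression noise, and any
dependence of expression on the clinical covariates other than response group.
Consequently, passing tests demonstrate that the pipeline's machinery is
correct and calibrated under its stated model — not that real whole-blood data
satisfy that model.

## Preprocessing

Probes not flagged expressed on any array are removed ("expressed" for
synthetic data means intensity above a configurable floor, default 5.0; real
detection calls are out of scope), along with an explicit blacklist. Quantile
normalization replaces each column's sorted values by the cross-column mean of
sorted values, with tied ranks receiving the average of the interpolated
reference values; the operation is idempotent (exactly so without ties).
Sample outliers are flagged when a sample's score on either of the first two
principal components exceeds `z_cutoff` (default 4) SDs of that component —
an automatic, testable stand-in for the visual PCA/dendrogram inspection such
studies describe — and an average-linkage dendrogram on 1 − Pearson distance
is returned for inspection. Outliers are reported, not silently dropped.

## Feature sets and standardization

Five contrasts: pretreatment expression, week-4 expression, the per-patient
log2 difference ("ratio" — identical to the intensity ratio in log space), and
clinical covariates at baseline or month 3. The nine clinical covariates
expand to ten features (sex, ACPA → {0,1}; smoking → past/current indicators
with never as reference; numerics pass through). Standardization parameters
(per-feature mean/SD) are estimated from training patients only and are refit
inside every outer CV fold; zero-variance training features are dropped with a
warning. Whether the original analysis standardized globally or per fold is
ambiguous; per-fold is the leakage-safe reading and is what the leakage tests
enforce.

## Nested cross-validation

Outer folds (default 10) are stratified by response; each class must have at
least `k_outer` members. Within an outer training fold: standardize, aggregate
to pathway features if requested, then select hyperparameters by mean ROC AUC
over an inner stratified loop (default 5-fold; ties go to the first grid
entry), refit on the full training fold, and score the held-out patients.
Every patient is scored exactly once across outer folds. Grids: 7 log-spaced
L2 penalty strengths (C = 10⁻³…10³) for the logistic families; {200, 500}
trees × {unlimited, depth 8} with √p features per split for the random
forest — deliberately small, honest defaults since no grids are prescribed.
The inner selection metric is ROC AUC, matching the headline metric.

Reported summaries follow the design's conventions: per-metric mean ± SEM with
SEM = SD(fold values)/√k, coefficient mean ± SD across folds for linear
families, and the nonresponder-detection curve (fraction of true nonresponders
detected vs fraction of good responders misclassified — the ROC curve with
nonresponder as the positive class). ROC AUC uses the Mann–Whitney convention
(ties count ½); constant score vectors return 0.5 with a warning. The
pathway-supported family is implemented as the mean of standardized member
features per pathway feeding the L2 grid — a deliberately simple aggregation
standing in for proprietary network-based variants, labeled as such.

## Coexpression networks

Unsigned weighted network: a_ij = |cor_ij|^β, zero diagonal, connectivity
k_i = Σ_{j≠i} a_ij. The soft threshold is chosen on an integer grid 1–20 by
the scale-free topology criterion: bin k into 10 equal-width bins, regress
log10 p(k) on log10(mean k per bin), and take the smallest β with a decreasing
fit of R² ≥ 0.85 **among βs whose mean connectivity stays ≥ 1**. The
connectivity floor is part of the criterion's fit-vs-density trade-off: as
β → ∞ the network empties and the log-log fit becomes spuriously scale-free,
so an unconstrained R² rule selects powers that zero out the TOM. When no β
reaches the target, the fallback is the largest β that keeps the network
connected on average (strongest penalization of weak correlations subject to
density), with a warning — on ~40-sample groups a max-R² fallback lands on
β ≈ 2, where the noise TOM is dense enough to merge all genes into one
spurious module. All thresholds are exposed in the API.

Topological overlap is the standard unsigned TOM (diagonal 1), computed by
matrix multiplication and verified against a triple-loop oracle. Modules come
from average-linkage clustering of 1 − TOM with a dynamic cut: branches
completing below a fixed dissimilarity cutoff (default 0.99 on the bounded
1 − TOM scale) become candidate modules, candidates smaller than
`min_module_size` (default 30) are left grey, and labels are assigned in
decreasing size order using the conventional color sequence. A fixed cutoff
rather than a merge-height quantile is deliberate: on null data the top
quantile of merge heights still admits large spurious clusters, whereas the
fixed cutoff leaves ≥ 90% of pure-noise genes grey while recovering planted
modules at ARI ≥ 0.8 (both are acceptance-tested).

Consensus networks: each group gets its own soft threshold and TOM; TOMs are
scaled so their 95th percentiles match the smallest across groups (scaling
factors ≤ 1 keep entries in [0, 1]) and combined by elementwise minimum, then
cut as usual. Per-group assignments come from the unscaled group TOMs. A group
module is reported as group-specific when more than `grey_fraction_threshold`
(default 0.5) of its members are grey in the consensus, together with the
fraction and the hypergeometric P value of its overlap with the consensus grey
set — a graded report rather than a single hard call. Whether a "consensus
group" should pool samples instead of combining per-group networks is an open
design question; combining networks is the default and pooling is available by
passing the pooled matrix to `build_network`.

Hub genes: the ⌈0.20·size⌉ most connected genes per module (grey excluded),
with connectivity ties broken lexicographically for determinism.

## Enrichment

Over-representation uses the upper-tail hypergeometric probability of the
observed overlap between a query list and each gene set, over a universe that
defaults to all genes surviving preprocessing. Term-size filters default to
[10, 2000]. Benjamini–Hochberg q values are emitted alongside raw P — raw P is
what such studies typically quote, but the multiplicity view should travel
with it. The external coexpression-evidence lookup is replaced by a
user-supplied two-column pair file; the reported statistic is the fraction of
hub genes with at least one evidence partner inside the same hub set.

## Numerical and degenerate-input policy

TSVs are tab-separated UTF-8 with `.` decimals and `NA` allowed only in
raw-scale inputs; floats are written at 17 significant digits and parsed with
a correctly-rounded reader, so write/read round-trips are bit-exact. Patient
ordering is lexicographic everywhere, which fixes fold assignment and output
order. Standardizer statistics are computed on contiguous arrays so they do
not depend on DataFrame block layout at the last bit (the leakage tests compare
checksums). Zero-variance genes abort network construction with the offending
names; constant matrices abort PCA; classes smaller than the fold count abort
CV with a stratification error. The whole network stage is deterministic given
its input; all simulation randomness flows from a single seed through
`numpy.random.SeedSequence` spawning, and the pipeline derives per-stage seeds
by hashing the stage name with the global seed.

## Problem sizes used in the checks

The acceptance-style tests and `scripts/acceptance.py` run at the sizes the
analyses were designed around where that matters — planted-module recovery at
2,000 genes × 60 samples, group-specific detection at 43 vs 42 samples over
ten cohorts, the signal classifier at 5,000 genes × 85 patients — and use
smaller cohorts where the quantity is size-insensitive: 800-gene cohorts for
the 20-seed null calibration (chance-level AUC does not depend on adding more
null genes) and a 2,500-gene cohort for the structural full-run checks. The
full 22,771-probe default remains the generator's study-scale setting.

## Known limitations

- The pathway-supported classifier is a mean-aggregation proxy, not a
  reimplementation of any specific published network classifier.
- The dynamic tree cut is the fixed-cutoff branch decomposition described
  above, not the full adaptive-height algorithm with branch-shape criteria;
  on data with nested module structure it will be more conservative.
- Enrichment does no GO-graph propagation; terms are treated as flat sets.
- The generator's independence assumptions (noise, factors across timepoints,
  covariates vs expression) are simplifications; see the generator section for
  what passing tests do and do not establish.
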