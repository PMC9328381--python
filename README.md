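# mtxresponse

Roughly a third of rheumatoid arthritis (RA) patients started on low-dose
methotrexate (MTX) do not benefit from it, yet the decision to escalate
therapy is typically deferred until month 6. `mtxresponse` is a tested,
reusable implementation of an early-biomarker analysis for this problem: given
whole-blood expression profiles at pretreatment and 4 weeks after MTX
initiation, plus baseline clinical covariates, it asks whether EULAR
nonresponse at 6 months can be classified from the *longitudinal change* in
expression, and which coexpressed gene modules are specific to nonresponders.

It is aimed at computational biologists who want to reproduce, stress-test, or
extend this class of paired-timepoint response analyses without access to the
original cohort: a first-class synthetic cohort generator emulates the study's
data structure (group sizes, group-conditional clinical covariates, DAS28-CRP /
EULAR labeling, planted coexpression modules, planted longitudinal signal), so
every stage is verifiable against known ground truth.

## What it computes

**Delta-expression classifiers.** For patient *p* and probe *g* the "ratio"
feature is the log2 difference Δ<sub>gp</sub> = x<sub>gp</sub><sup>wk4</sup> −
x<sub>gp</sub><sup>pre</sup>. Three model families — L2-regularized logistic
regression, random forest, and a pathway-supported variant (pathway-mean
aggregation of standardized features feeding the L2 model) — are evaluated
with stratified nested cross-validation (10 outer folds; hyperparameters
chosen by ROC AUC in an inner 5-fold loop; standardization refit inside every
outer training fold). Reported: balanced accuracy and ROC AUC as mean ± SEM
over outer folds (SEM = SD/√10), per-feature coefficients as mean ± SD, and
the clinical trade-off curve of nonresponders detected vs good responders
misclassified.

**Weighted coexpression networks (from scratch).** Pearson correlation →
unsigned adjacency a<sub>ij</sub> = |cor<sub>ij</sub>|<sup>β</sup> with β
chosen by the scale-free topology criterion (R² of the log p(k) vs log k fit,
subject to a mean-connectivity floor) → topological overlap
TOM<sub>ij</sub> = (Σ<sub>u</sub> a<sub>iu</sub>a<sub>uj</sub> + a<sub>ij</sub>) /
(min(k<sub>i</sub>, k<sub>j</sub>) + 1 − a<sub>ij</sub>) → average-linkage
clustering of 1 − TOM with a dynamic, minimum-size-respecting tree cut.
Consensus networks (percentile-scaled per-group TOMs combined elementwise by
minimum) identify modules present in nonresponders but unassigned ("grey") in
the consensus of both groups; module pairs are compared by upper-tail
hypergeometric P values, and hub genes are the top 20% of each module by
connectivity k<sub>i</sub> = Σ<sub>j≠i</sub> a<sub>ij</sub>.

**Enrichment.** Hypergeometric over-representation of hub/module gene lists
against GMT gene sets (raw P and Benjamini–Hochberg q), plus a
prior-coexpression evidence check against a user-supplied pair list.

**Clinical labels.** DAS28-CRP = 0.56·√TJC28 + 0.28·√SJC28 + 0.36·ln(CRP+1) +
0.014·VAS + 0.96, and the standard EULAR good/moderate/none grid on the
baseline → month-6 trajectory.

## Worked example

Simulate a study-sized cohort (85 patients, 2,000 probes, one shared and one
nonresponder-only module, 50 delta-signal genes) and run every stage:

```yaml
# demo.yaml
out_dir: run
seed: 7
simulation:
  n_good: 42
  n_nonresponder: 43
  n_genes: 2000
  module_spec:
    - {size: 150, correlation: 0.6}
    - {size: 100, correlation: 0.6, restriction: nonresponder_only}
  n_signal_genes: 50
  signal_effect: 1.0
k_outer: 10
k_inner: 5
```

```bash
mtxresponse --verbose run-all --config demo.yaml
```

prints one structured line per stage:

```
stage=simulate n_genes=2000 n_patients=85 seed=989737829
stage=preprocess probes_in=2000 probes_out=1981 outliers=0
stage=features contrast=expr_ratio n_features=1981 n_patients=85
stage=classify family=l2_logistic auc=0.980+/-0.015 bacc=0.945+/-0.033
stage=network beta=5 modules=2 group_specific=1
```

Reading the output: 19 of the 2,000 simulated probes were unexpressed on every
array and removed by QC; the delta-expression L2 classifier recovers the
planted nonresponse signal with ROC AUC 0.980 ± 0.015 (mean ± SEM over the 10
outer folds) and balanced accuracy 0.945 ± 0.033; the network stage picks
β = 5, finds two modules in the nonresponder group, and reports exactly one of
them as nonresponder-specific. `run/group_specific_modules.tsv` shows it is
the planted one — all of its 113 member genes are grey in the consensus
network (hypergeometric P = 7.6 × 10⁻⁵ for the overlap with the grey set):

```
module  size  grey_fraction  grey_overlap_p
blue    113   1.0            7.5686331816791e-05
```

The run directory also contains the per-fold metrics with chosen
hyperparameters (`cv_folds.tsv`), the pooled detection trade-off curve
(`detection_curve.tsv`), per-gene module/connectivity/hub assignments
(`modules.tsv`), the scale-free fit table, the gene dendrogram in Newick, and
a `manifest.json` of artifact checksums — rerunning with the same config and
seed reproduces them byte-for-byte.

Each stage is also available as a library function
(`mtxresponse.simulate.simulate_cohort`, `preprocess.run_qc`,
`features.delta_expression`, `classify.nested_cv`, `network.build_network`,
`enrichment.hypergeometric_enrichment`, ...) and as an individual subcommand
(`simulate`, `preprocess`, `features`, `classify`, `network`, `enrich`).

## Layout

```
src/mtxresponse/
  data.py        containers + TSV I/O (ExpressionMatrix, SampleTable, DeltaMatrix)
  simulate.py    synthetic cohort generator (clinical + expression ground truth)
  preprocess.py  probe filtering, quantile normalization, outlier detection
  features.py    delta/timepoint/clinical feature sets, leakage-safe standardization
  classify.py    nested CV, metrics, detection curve, pathway aggregation
  network.py     WGCNA: soft threshold, TOM, tree cut, consensus, hubs
  enrichment.py  GMT, hypergeometric ORA, coexpression-evidence check
  pipeline.py    orchestration, manifest, per-stage seeding
  cli.py         click entry points
docs/methods.md  model, parameter and design documentation
```
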