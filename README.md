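# e2fscore

PCA-based scoring of E2F pathway activity in lung adenocarcinoma, with
the statistical machinery needed to develop and validate such a score as
a prognostic and treatment-predictive biomarker: cross-platform (fresh
frozen vs FFPE) concordance filtering, PC1 signature training and
projection, median-cutoff risk classification, Kaplan–Meier/log-rank/Cox
survival validation including the treatment × biomarker interaction
test, and the associated power calculations. Everything is exercised on
seeded synthetic cohorts whose generators are first-class, tested
package code.

The package is for biostatisticians and computational biologists who
want a transparent, reproducible reference implementation of this class
of signature-scoring pipeline — the kind built around NanoString assays
of a few dozen genes — without access to restricted clinical cohorts.

## The model

**Score.** Given a gene-by-sample matrix X restricted to a signature of
G genes, genes are z-scored within the cohort (platforms have
incompatible absolute scales) and the score of sample *i* is the PC1
projection

s_i = Σ_g w_g z_gi,

where **w** is the unit-norm leading eigenvector of the gene–gene
correlation matrix of the training cohort, sign-oriented so that
mean(w) ≥ 0 (higher score = coordinate up-regulation of E2F targets).
Patients are classified *high* when their score strictly exceeds the
median (more generally, a chosen percentile) of their cohort's score
distribution, giving ~50% biomarker prevalence.

**Concordance filter.** For matched FF/FFPE measurements of the same
patients, each gene's cross-platform Pearson (and Spearman) correlation
is computed across patients; genes with r < 0.5 are dropped. On the
bundled 106-candidate-gene design with 32 poorly concordant genes this
leaves the 74-gene signature.

**Survival validation.** Prognostic effect: log-rank test and Cox HR
(high vs low, Efron ties, optional stage/age/sex adjustment) with KM
medians and 5-year rates (Greenwood log-log CIs). Predictive effect: Cox
model with treatment, biomarker, and their interaction; exp(interaction
coefficient) is the ratio of treatment hazard ratios between biomarker
groups, reported with its Wald CI/p plus stratified per-group ACT-vs-none
effects.

**Power.** Prognostic power uses the Schoenfeld approximation
power = Φ(|ln HR|·√(D·p(1−p)) − z₁₋α/₂) with D events and prevalence p,
and its closed-form inverse for the minimal detectable HR. The
predictive effect size follows from exponential survival, where a cell's
hazard is proportional to −ln(5-year survival): with control-arm rates
66%/20% (low/high) and treated rates 66%/66%, the implied ratio of
treatment HRs is ln(0.66)/ln(0.20) ≈ 0.26. Power for the interaction
test is estimated by seeded simulation.

## Worked example

`examples/02_train_and_score.py` trains the score on a simulated
200-patient cohort:

```
signature genes: 74
PC1 variance explained: 48.9%
loading range: 0.059 to 0.145
training score median: 0.534
labelled high: 100 / 200
score vs latent activity correlation: 0.993
```

The loadings are mostly positive and the score recovers the latent
proliferation activity that drives both expression and hazard (r =
0.99); the median cutoff labels exactly half the cohort high.

`examples/04_predictive_trial.py` runs the interaction test on a
simulated 800-patient randomized trial built from the design's cell-wise
5-year survival rates:

```
ACT vs none in  low group: HR 1.32 (1.00, 1.72), log-rank p 0.045
ACT vs none in high group: HR 0.31 (0.25, 0.39), log-rank p 2.1e-24
interaction HR ratio (high/low): 0.24 (0.16, 0.34), p 1.9e-15
analytic ratio implied by the design: 0.26
```

Adjuvant chemotherapy benefit is concentrated in high-score patients
(HR 0.31) and absent in low-score patients; the interaction ratio
estimate (0.24) matches the closed-form value (0.26) implied by the
generating rates.

The other examples cover the concordance screen (`01`), prognostic
validation and the percentile sweep (`03`), power analysis (`05`), and
the full orchestrated pipeline (`06`). The pipeline is also available as
a CLI:

```bash
e2fscore run-all --config examples/demo_config.yaml --outdir out/
e2fscore power --n-events 287 --surv5 0.66 0.20 0.66 0.66
```

Every run is deterministic given its seed, and `run-all` writes a
manifest with a sha256 per artifact.

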