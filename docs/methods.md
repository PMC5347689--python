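# Methods

## Scoring model

The scoring system assumes signature-gene expression is driven by one
dominant latent factor (E2F-driven proliferation). Training standardizes
each gene within the training cohort (mean 0, SD 1, ddof = 1) and
eigendecomposes the gene–gene covariance of the standardized data
(equivalently the correlation matrix). The leading eigenvector is the
gene-weight vector; the score is the dot product of those weights with a
sample's standardized gene vector. PC1's sign is not identifiable, so
weights are oriented to non-negative mean, which makes a higher score
correspond to coordinate up-regulation of the signature; variance
explained (λ₁/Σλ) and the training-score median are stored with the
model.

**Projection.** Validation cohorts are standardized against
*themselves* before projection. This is a deliberate transfer rule:
cohorts measured on different platforms (microarray FF, NanoString FFPE)
have incompatible absolute scales, and per-cohort z-scoring makes score
distributions comparable without any cross-platform calibration step.
Applying the training cohort's means/SDs instead is supported
(`use_training_params=True`) for sensitivity analysis. Similarly, the
classification threshold is by default a percentile of the cohort being
classified (median → 50% prevalence of "high", the prevalence the power
calculations assume); a training-derived threshold can be applied by
reusing the stored training median.

**Tie rule.** "High" means score strictly above the threshold; samples
exactly at it are labelled low, conservative toward recommending
treatment. Percentiles use linear interpolation between order
statistics.

## Normalization

NanoString-style count matrices are normalized by housekeeping genes:
each sample's scale factor is the geometric mean of its control-gene
counts divided by the across-sample geometric mean of those per-sample
geometric means; all counts are divided by the factor and then
log2(x + 1)-transformed. The +1 offset handles zero counts. Per-sample
loading distortions are removed exactly by this scheme (the scaling
invariance test uses distortions with unit geometric mean, since a
global rescale of the whole cohort interacts with the +1 offset at the
third decimal and is not the artifact the normalization targets).
Zero-variance genes are a hard error during standardization, naming the
gene.

## Concordance filter

For each gene, Pearson and Spearman correlations between its FF and
FFPE profiles are computed across paired patients. Pearson decides
removal by default (both are always reported; `method="spearman"` or
`"both"` are available): a gene is retained iff its decisive correlation
is ≥ the threshold (default 0.5), i.e. removal applies to r strictly
below the cut. The filter is monotone in the threshold.

## Synthetic cohorts

The generators encode the statistical structure the analysis assumes,
not the chemistry of the assays:

- **Survival cohorts** (`generate_cohort`): latent activity a ~ N(0,1)
  per patient; signature gene j measures baseline + w_j·a + N(0, σ)
  with σ = 0.6 on the log2 scale and weights spread over [0.3, 1.0];
  18 control genes have zero loading and σ/10 noise ("highly
  invariant"). Overall survival is exponential with hazard
  0.008/month · exp(β·a + stage log-HR), stages drawn from
  (0.55, 0.25, 0.20) over I/II/III-IV with log-HRs (0, 0.4, 0.9),
  administratively censored at 120 months. Progression uses a 1.5×
  hazard on the same linear predictor, truncated at death. FFPE cohorts
  are emitted as 2^(log2 value) counts times a lognormal(0, 0.3)
  per-sample loading factor, so housekeeping normalization has real work
  to do; FF cohorts are emitted on log2 scale directly.
- **Randomized trials** (`generate_trial`): four cells from exact
  deterministic rounding of (treat fraction × biomarker fraction) — not
  Bernoulli draws, so allocation noise never contaminates power
  estimates. Cell hazards are −ln(5-year survival)/60 months, making the
  analytic 60-month survival reproduce the design rates to machine
  precision; default follow-up is 120 months.
- **Paired FF/FFPE sets** (`generate_paired_set`): FF values standard
  normal per gene; FFPE = ρ·FF + √(1−ρ²)·noise with a per-gene target
  ρ. The concordance-screen fixture uses ρ = 0.9 for concordant genes
  and ρ = −0.3 for discordant ones: both levels sit ≳5 Fisher-z SDs from
  the 0.5 cut at 36 paired samples, so the 74/32 split is stable across
  seeds rather than depending on a particular draw.

What the generators do *not* emulate: probe-level microarray structure,
batch effects, RNA-degradation chemistry, non-proportional hazards,
informative censoring, or correlated noise between genes beyond the
single latent factor. Passing tests therefore demonstrate correctness of
the statistical machinery under its own assumptions, not robustness of
the signature on real tissue.

## Survival analysis

Kaplan–Meier, log-rank, and Cox fits are computed with lifelines. Median
survival is the smallest t with S(t) ≤ 0.5, reported as "NR" (not
reached) when the curve never drops that far. Horizon (5-year) rates
carry exponential-Greenwood log-log 95% CIs; hazard-ratio CIs are Wald
on the log scale. Ties use Efron's method (simulated times are
continuous, so this matters only for hand-built fixtures). Monotone
likelihood — an arm or biomarker group with no events — raises an
explicit error instead of returning a runaway estimate. Combined-cohort
analyses pool patient records by concatenation without cohort
stratification. Proportional-hazards diagnostics are out of scope.

The interaction model is hazard ∝ exp(β₁·treated + β₂·high +
β₃·treated·high [+ covariates]); exp(β₃) is the ratio of treatment HRs
(high over low) with Wald CI and p. Stratified per-group ACT-vs-none
fits and log-rank tests accompany it in reports.

## Power

Prognostic power uses the Schoenfeld normal approximation in its
standard one-tail form, power = Φ(|ln HR|·√(D·p(1−p)) − z₁₋α/₂); the
contribution of the opposite tail is negligible for any design of
practical interest, and at HR = 1 the formula returns α/2 by
construction. The detectable-HR inverse is exact. At the 68-event design
point the formula gives 83.1% power for HR 2.03 — slightly above the
80% conventionally quoted for that design, as expected from a formula
that ignores accrual.

Interaction-test power is estimated by simulation: each replicate draws
a fresh trial from the design (child seeds spawned from the simulation
seed),
fits the interaction Cox model, and records rejection at two-sided α.
Replicates with inestimable models are counted and reported; they are
excluded from the denominator only while rare (< 1% of replicates),
otherwise the full denominator is kept so the failure rate remains
visible. An independent normal approximation from expected per-cell
event counts (`analytic_interaction_power`) cross-checks the simulation
in tests. Simulation sizes in the test suite (2000 null replicates of
n = 200 for test size; n = 20000 for parameter-recovery checks) were
chosen to keep Monte-Carlo error well below the assertion tolerances.

## Pipeline

`run_pipeline` fans a single global seed out into named per-stage child
seeds (numpy `SeedSequence`), so each stage is independently
reproducible. Artifacts (models as JSON, scores as CSV, reports and
curves as TSV) are listed in a manifest with sha256 hashes; a rerun with
identical config and seed is byte-identical, and a completed run is
detected via the manifest and skipped (whole-run cache keyed on config
hash + seed — per-stage caching was considered and dropped as not worth
the complexity at these run times). Any stage failure aborts with the
stage and offending input named in the log; the concordance stage logs
genes in/out.

## Known limitations

- The linear-Gaussian single-factor expression model makes PC1 recovery
  well-posed by construction; multi-factor or nonlinear structure would
  lower variance explained and weaken latent-activity recovery.
- Per-cohort standardization assumes each cohort is large and
  representative enough for stable gene means/SDs; very small cohorts
  inherit noisy thresholds.
- The exponential survival model has constant hazards; power numbers for
  designs with strong accrual or late-separating curves will differ.
- The 74-gene identities here are synthetic placeholders; the package
  reproduces the machinery and design arithmetic of such a signature,
  not the published gene list or its loadings.
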