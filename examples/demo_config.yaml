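# Demo pipeline configuration: small synthetic cohorts per platform,
# a paired FF/FFPE technical-optimization set for the concordance screen,
# a randomized 2x2 trial, and the power analyses.
seed: 1
endpoint: os
filter_threshold: 0.5
percentiles: [25, 30, 35, 40, 45, 50, 55, 60, 65, 70, 75]
n_candidate_genes: 106
n_discordant_genes: 32
n_control_genes: 18
paired_n_patients: 36
cohort_defaults:
  latent_hazard_coef: 0.7
training_ff:
  cohort_id: FF_TRAIN
  n_patients: 200
training_ffpe:
  cohort_id: FFPE_TRAIN
  n_patients: 150
validation:
  - cohort_id: FF_VAL1
    platform: FF
    n_patients: 150
  - cohort_id: FFPE_VAL1
    platform: FFPE
    n_patients: 100
trial:
  n_patients: 400
  surv5: [0.66, 0.20, 0.66, 0.66]
prognostic_power:
  - n_events: 287
    prevalence: 0.5
    hazard_ratio: 1.4
    alpha: 0.05
  - n_events: 68
    prevalence: 0.5
    hazard_ratio: 2.03
    alpha: 0.05
predictive_power:
  n_reps: 60
  alpha: 0.05
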