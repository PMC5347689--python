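"""Seeded synthetic cohorts with the statistical structure the scoring
pipeline assumes.

Three generators cover the study designs the pipeline is validated on:

* :func:`generate_cohort` — a survival cohort whose expression matrix is
  driven by a latent proliferation factor (the quantity the PC1 score is
  meant to recover) and whose hazard depends log-linearly on that factor.
* :func:`generate_trial` — a randomized 2x2 (treatment x biomarker) trial
  parameterized directly by cell-wise 5-year survival rates, the
  parameterization used in predictive-biomarker sample-size work.
* :func:`generate_paired_set` — matched FF/FFPE measurements with a
  per-gene target correlation, emulating a technical-optimization cohort
  used to screen genes for cross-platform concordance.

All generators are deterministic given their spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, PairedTissueSet, validate_clinical

STAGE_LEVELS = ("I", "II", "III/IV")


def _check_prob_vector(p, name: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if (p < 0).any() or abs(p.sum() - 1.0) > 1e-12:
        raise ValueError(f"{name} must be non-negative and sum to 1 (got sum {p.sum()!r})")
    return p


@dataclass
class CohortSpec:
    """Parameters of a latent-factor survival cohort.

    The latent proliferation activity ``a_i`` is standard normal per
    patient.  Signature gene ``j`` measures ``gene_weights[j] * a_i`` plus
    Gaussian noise; control genes do not load on the factor and have a
    tenth of the noise ("highly invariant").  Overall survival is
    exponential with hazard ``baseline_hazard * exp(latent_hazard_coef *
    a_i + stage_log_hr)``, administratively censored at
    ``followup_months``.
    """

    n_patients: int
    platform: str = "FF"
    cohort_id: str = "SYN"
    n_signature_genes: int = 74
    n_control_genes: int = 18
    gene_weights: np.ndarray | None = None  # default: linspace(0.3, 1.0)
    noise_sd: float = 0.6
    latent_hazard_coef: float = 0.5
    stage_probs: tuple[float, float, float] = (0.55, 0.25, 0.20)
    stage_log_hrs: tuple[float, float, float] = (0.0, 0.4, 0.9)
    baseline_hazard: float = 0.008  # per month; median OS ~ 7 yr for stage I at a=0
    followup_months: float = 120.0
    pfs_hazard_multiplier: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if self.n_signature_genes <= 0 or self.n_control_genes < 0:
            raise ValueError("gene counts must be positive")
        if self.noise_sd <= 0 or self.baseline_hazard <= 0 or self.followup_months <= 0:
            raise ValueError("noise_sd, baseline_hazard and followup_months must be positive")
        _check_prob_vector(self.stage_probs, "stage_probs")
        if self.gene_weights is None:
            self.gene_weights = np.linspace(0.3, 1.0, self.n_signature_genes)
        else:
            self.gene_weights = np.asarray(self.gene_weights, dtype=float)
            if self.gene_weights.shape != (self.n_signature_genes,):
                raise ValueError("gene_weights length must equal n_signature_genes")


def generate_cohort(spec: CohortSpec) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Draw one cohort: expression matrix plus clinical table.

    FF cohorts are returned on log2 scale (microarray-like); FFPE cohorts
    are returned as NanoString-like positive counts, ``2**x`` times a
    lognormal per-sample loading factor, so that housekeeping
    normalization has real work to do.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients

    a = rng.standard_normal(n)  # latent proliferation activity

    sig_ids = [f"E2F_G{j + 1:03d}" for j in range(spec.n_signature_genes)]
    ctrl_ids = [f"CTRL_{j + 1:02d}" for j in range(spec.n_control_genes)]
    sample_ids = [f"{spec.cohort_id}_{i + 1:04d}" for i in range(n)]

    base_sig = rng.uniform(6.0, 10.0, spec.n_signature_genes)
    base_ctrl = rng.uniform(8.0, 12.0, spec.n_control_genes)

    sig = (
        base_sig[:, None]
        + spec.gene_weights[:, None] * a[None, :]
        + rng.normal(0.0, spec.noise_sd, (spec.n_signature_genes, n))
    )
    ctrl = base_ctrl[:, None] + rng.normal(0.0, spec.noise_sd / 10.0, (spec.n_control_genes, n))
    log2_values = np.vstack([sig, ctrl]) if spec.n_control_genes else sig

    if spec.platform == "FFPE":
        sample_factor = np.exp(rng.normal(0.0, 0.3, n))
        values = np.power(2.0, log2_values) * sample_factor[None, :]
        scale = "raw_counts"
    else:
        values = log2_values
        scale = "log2"

    expr = ExpressionMatrix(
        pd.DataFrame(values, index=sig_ids + ctrl_ids, columns=sample_ids),
        platform=spec.platform,
        scale=scale,
    )

    stage_idx = rng.choice(len(STAGE_LEVELS), size=n, p=np.asarray(spec.stage_probs))
    stage_lhr = np.asarray(spec.stage_log_hrs)[stage_idx]

    os_rate = spec.baseline_hazard * np.exp(spec.latent_hazard_coef * a + stage_lhr)
    os_raw = rng.exponential(1.0 / os_rate)
    os_event = (os_raw <= spec.followup_months).astype(int)
    os_months = np.minimum(os_raw, spec.followup_months)

    # Progression precedes death stochastically: PFS uses an inflated
    # hazard on the same linear predictor, truncated at the death time.
    pfs_rate = os_rate * spec.pfs_hazard_multiplier
    prog_raw = rng.exponential(1.0 / pfs_rate)
    pfs_raw = np.minimum(prog_raw, os_raw)
    pfs_event = (pfs_raw <= spec.followup_months).astype(int)
    pfs_months = np.minimum(pfs_raw, spec.followup_months)

    clinical = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "cohort": spec.cohort_id,
            "platform": spec.platform,
            "stage": [STAGE_LEVELS[i] for i in stage_idx],
            "arm": "none",
            "os_months": os_months,
            "os_event": os_event,
            "pfs_months": pfs_months,
            "pfs_event": pfs_event,
            "latent_activity": a,
        }
    )
    return expr, validate_clinical(clinical)


@dataclass
class TrialDesign:
    """A randomized 2x2 trial parameterized by cell 5-year survival.

    ``surv5`` orders the cells (low, control), (high, control),
    (low, treated), (high, treated).  Cell hazards are
    ``-ln(surv5) / horizon_months`` under the exponential model, so the
    analytic survival at the horizon reproduces the design rates exactly.
    Allocation uses exact deterministic rounding, not Bernoulli draws.
    """

    n_patients: int
    surv5: tuple[float, float, float, float] = (0.66, 0.20, 0.66, 0.66)
    treat_fraction: float = 0.5
    high_fraction: float = 0.5
    horizon_months: float = 60.0
    followup_months: float = 120.0
    cohort_id: str = "TRIAL"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if not all(0.0 < s < 1.0 for s in self.surv5):
            raise ValueError("all surv5 rates must lie strictly in (0, 1)")
        for name in ("treat_fraction", "high_fraction"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.horizon_months <= 0 or self.followup_months <= 0:
            raise ValueError("horizons must be positive")

    @property
    def cell_hazards(self) -> np.ndarray:
        return -np.log(np.asarray(self.surv5)) / self.horizon_months


def generate_trial(design: TrialDesign) -> pd.DataFrame:
    """Simulate the trial; returns a clinical table with ``arm`` and
    ``e2f_group`` columns populated."""
    n = design.n_patients
    n_treat = int(round(n * design.treat_fraction))
    arms = []
    for treated, n_arm in ((0, n - n_treat), (1, n_treat)):
        n_high = int(round(n_arm * design.high_fraction))
        arms.append((treated, 0, n_arm - n_high))
        arms.append((treated, 1, n_high))

    rng = np.random.default_rng(design.seed)
    hazards = design.cell_hazards
    rows = []
    idx = 0
    for treated, high, n_cell in arms:
        lam = hazards[2 * treated + high]
        raw = rng.exponential(1.0 / lam, n_cell)
        event = (raw <= design.followup_months).astype(int)
        months = np.minimum(raw, design.followup_months)
        for t, e in zip(months, event):
            idx += 1
            rows.append(
                {
                    "sample_id": f"{design.cohort_id}_{idx:05d}",
                    "cohort": design.cohort_id,
                    "platform": "FFPE",
                    "stage": "unknown",
                    "arm": "ACT" if treated else "none",
                    "e2f_group": "high" if high else "low",
                    "os_months": t,
                    "os_event": e,
                    "pfs_months": t,
                    "pfs_event": e,
                }
            )
    return validate_clinical(pd.DataFrame(rows))


@dataclass
class PairedTissueSpec:
    """Matched FF/FFPE design with per-gene target correlation.

    FF values are standard normal; FFPE values are
    ``rho * FF + sqrt(1 - rho**2) * noise`` per gene, so the population
    FF-FFPE correlation of gene ``g`` equals ``target_correlations[g]``.
    """

    n_patients: int = 36
    n_genes: int = 106
    target_correlations: np.ndarray | None = None
    gene_ids: list[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0 or self.n_genes <= 0:
            raise ValueError("n_patients and n_genes must be positive")
        if self.gene_ids is not None and len(self.gene_ids) != self.n_genes:
            raise ValueError("gene_ids length must equal n_genes")
        if self.target_correlations is None:
            self.target_correlations = np.full(self.n_genes, 0.8)
        else:
            self.target_correlations = np.asarray(self.target_correlations, dtype=float)
            if self.target_correlations.shape != (self.n_genes,):
                raise ValueError("target_correlations length must equal n_genes")
            if (np.abs(self.target_correlations) > 1.0).any():
                raise ValueError("target correlations must lie in [-1, 1]")


def generate_paired_set(spec: PairedTissueSpec) -> PairedTissueSet:
    rng = np.random.default_rng(spec.seed)
    gene_ids = spec.gene_ids or [f"GENE_{j + 1:03d}" for j in range(spec.n_genes)]
    sample_ids = [f"MLTO_{i + 1:03d}" for i in range(spec.n_patients)]

    ff = rng.standard_normal((spec.n_genes, spec.n_patients))
    noise = rng.standard_normal((spec.n_genes, spec.n_patients))
    rho = spec.target_correlations[:, None]
    ffpe = rho * ff + np.sqrt(1.0 - rho**2) * noise

    return PairedTissueSet(
        ff=ExpressionMatrix(pd.DataFrame(ff, index=gene_ids, columns=sample_ids), "FF", "log2"),
        ffpe=ExpressionMatrix(pd.DataFrame(ffpe, index=gene_ids, columns=sample_ids), "FFPE", "log2"),
    )


def concordance_screen_targets(
    n_genes: int = 106, n_discordant: int = 32, rho_good: float = 0.9, rho_poor: float = -0.3
) -> np.ndarray:
    """Target correlations for a concordance-screen fixture: the first
    ``n_genes - n_discordant`` genes reproduce well across platforms, the
    remainder are poorly concordant.  The two levels sit far enough from
    the conventional 0.5 cut that sampling noise at three dozen paired
    samples essentially never moves a gene across it."""
    if n_discordant > n_genes:
        raise ValueError("n_discordant cannot exceed n_genes")
    targets = np.full(n_genes, rho_good)
    if n_discordant:
        targets[-n_discordant:] = rho_poor
    return targets
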