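"""Power and sample-size machinery for prognostic and predictive effects.

Prognostic power uses the Schoenfeld approximation for a two-group
survival comparison: with D events, biomarker prevalence p and hazard
ratio HR, the two-sided level-alpha test has

    power = Phi(|ln HR| * sqrt(D * p * (1 - p)) - z_{1 - alpha/2})

(the standard one-tail form; the opposite tail is negligible for any
design worth running).  Its inverse gives the minimal detectable HR.

The predictive effect size is expressed as a ratio of treatment hazard
ratios between biomarker groups.  Under exponential survival a cell's
hazard is proportional to -ln(5-year survival), so the ratio follows in
closed form from the four cell rates; power for the interaction test is
estimated by simulation (generate a trial, fit the interaction Cox
model, count rejections).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .simulate import TrialDesign, generate_trial
from .survival import CoxConvergenceError, interaction_test


@dataclass
class PrognosticPowerSpec:
    n_events: int
    prevalence: float = 0.5
    hazard_ratio: float = 1.4
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_events <= 0:
            raise ValueError("n_events must be positive")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


def prognostic_power(
    n_events: int, prevalence: float = 0.5, hazard_ratio: float = 1.4, alpha: float = 0.05
) -> float:
    """Schoenfeld power of a two-sided level-alpha log-rank/Cox test."""
    spec = PrognosticPowerSpec(n_events, prevalence, hazard_ratio, alpha)
    z_alpha = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    ncp = abs(np.log(spec.hazard_ratio)) * np.sqrt(
        spec.n_events * spec.prevalence * (1.0 - spec.prevalence)
    )
    return float(stats.norm.cdf(ncp - z_alpha))


def detectable_hr(
    n_events: int, prevalence: float = 0.5, power: float = 0.80, alpha: float = 0.05
) -> float:
    """Minimal hazard ratio (> 1) detectable at the requested power.

    Exact inverse of :func:`prognostic_power`:
    HR = exp((z_{1-alpha/2} + z_power) / sqrt(D p (1-p))).
    """
    if n_events <= 0:
        raise ValueError("n_events must be positive")
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must lie in (0, 1)")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if not alpha / 2.0 < power < 1.0:
        raise ValueError(f"power must lie in (alpha/2, 1); got {power}")
    z_alpha = stats.norm.ppf(1.0 - alpha / 2.0)
    z_power = stats.norm.ppf(power)
    return float(np.exp((z_alpha + z_power) / np.sqrt(n_events * prevalence * (1.0 - prevalence))))


def hr_ratio_from_survival(surv5, horizon_months: float = 60.0) -> float:
    """Ratio of treatment HRs implied by four cell 5-year survival rates.

    ``surv5`` orders cells (low, control), (high, control), (low,
    treated), (high, treated).  Exponential hazards are proportional to
    -ln(rate)/horizon; the horizon cancels in the ratio

        [ln(s_trt_high) / ln(s_ctrl_high)] / [ln(s_trt_low) / ln(s_ctrl_low)].
    """
    s = np.asarray(surv5, dtype=float)
    if s.shape != (4,):
        raise ValueError("surv5 must contain exactly four rates")
    if not np.all((s > 0.0) & (s < 1.0)):
        raise ValueError("all survival rates must lie strictly in (0, 1)")
    if horizon_months <= 0:
        raise ValueError("horizon must be positive")
    ctrl_low, ctrl_high, trt_low, trt_high = s
    return float((np.log(trt_high) / np.log(ctrl_high)) / (np.log(trt_low) / np.log(ctrl_low)))


@dataclass
class PredictivePowerSpec:
    """Simulation design for interaction-test power."""

    design: TrialDesign
    alpha: float = 0.05
    n_reps: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_reps < 1:
            raise ValueError("n_reps must be positive")


@dataclass
class PredictivePowerResult:
    power: float
    mc_se: float
    n_reps: int
    n_rejected: int
    n_failed: int  # replicates with inestimable interaction models

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"power={self.power:.3f} (MC SE {self.mc_se:.3f}, {self.n_reps} reps, {self.n_failed} failed)"


def predictive_power_sim(spec: PredictivePowerSpec) -> PredictivePowerResult:
    """Monte-Carlo power of the treatment x biomarker interaction test.

    Each replicate simulates a fresh trial from ``spec.design`` (with a
    child seed spawned from ``spec.seed``), fits the interaction Cox
    model, and records rejection at two-sided ``alpha``.  Replicates with
    inestimable models (empty or event-free cells) are counted and
    excluded from the denominator only when they make up under 1% of
    replicates; beyond that the design itself is flagged as inadequate.
    """
    seeds = np.random.SeedSequence(spec.seed).generate_state(spec.n_reps) % (2**31)
    rejected = 0
    failed = 0
    for s in seeds:
        design = replace(spec.design, seed=int(s))
        clinical = generate_trial(design)
        try:
            res = interaction_test(clinical, "e2f_group", endpoint="os", per_group=False)
        except CoxConvergenceError:
            failed += 1
            continue
        if res.p < spec.alpha:
            rejected += 1
    if failed == spec.n_reps:
        raise RuntimeError("all replicates produced inestimable models; design inadequate")
    # Failures are dropped from the denominator only while rare (< 1% of
    # replicates); a design failing more often than that keeps the full
    # denominator so the failure rate is visible in the power estimate.
    denom = spec.n_reps - failed if failed / spec.n_reps < 0.01 else spec.n_reps
    power = rejected / denom
    mc_se = float(np.sqrt(power * (1.0 - power) / denom))
    return PredictivePowerResult(
        power=float(power), mc_se=mc_se, n_reps=denom, n_rejected=rejected, n_failed=failed
    )


def analytic_interaction_power(
    design: TrialDesign, alpha: float = 0.05
) -> float:
    """Normal approximation to interaction-test power from expected
    per-cell event counts: power = Phi(|ln R| / sqrt(sum 1/d_i) - z).

    Used as an independent cross-check of the simulation, not as its
    replacement.
    """
    n = design.n_patients
    n_treat = round(n * design.treat_fraction)
    cells = []
    for treated, n_arm in ((0, n - n_treat), (1, n_treat)):
        n_high = round(n_arm * design.high_fraction)
        cells.append((treated, 0, n_arm - n_high))
        cells.append((treated, 1, n_high))
    hazards = design.cell_hazards
    d = []
    for treated, high, n_cell in cells:
        lam = hazards[2 * treated + high]
        d.append(n_cell * (1.0 - np.exp(-lam * design.followup_months)))
    log_ratio = np.log(hr_ratio_from_survival(design.surv5, design.horizon_months))
    se = np.sqrt(sum(1.0 / di for di in d))
    z_alpha = stats.norm.ppf(1.0 - alpha / 2.0)
    return float(stats.norm.cdf(abs(log_ratio) / se - z_alpha))
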