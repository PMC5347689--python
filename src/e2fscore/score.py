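"""PC1-based E2F score: training, projection, classification, concordance.

The score of a sample is its projection onto the first principal
component (PC1) of the standardized signature genes.  Loadings are
trained once per platform on a training cohort; validation cohorts are
standardized per cohort (platforms have incompatible absolute scales)
and projected with the training loadings.  Classification thresholds the
score at a percentile of the classified cohort's own distribution —
median by default, which fixes the prevalence of "high" at ~50%.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, ScoreSet
from .preprocess import StandardizationParams, standardize_genes
from . import survival as _survival


@dataclass
class SignatureModel:
    """Trained scoring system: gene order, unit-norm PC1 loadings,
    orientation, variance explained, and the training-score median.

    The sign of PC1 is not identifiable; loadings are oriented so their
    mean is non-negative, making a higher score track coordinate
    up-regulation of the signature genes.
    """

    platform: str
    gene_ids: list[str]
    loadings: np.ndarray
    orientation_sign: int
    pct_variance_pc1: float
    training_cohort_id: str
    training_score_median: float
    standardization: StandardizationParams

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, dtype=float)
        if abs(np.linalg.norm(self.loadings) - 1.0) > 1e-9:
            raise ValueError("loadings must be unit-norm")
        if self.loadings.mean() < 0:
            raise ValueError("loadings must be oriented to non-negative mean")
        if not 0.0 < self.pct_variance_pc1 <= 1.0 + 1e-12:
            raise ValueError("pct_variance_pc1 must lie in (0, 1]")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "platform": self.platform,
            "gene_ids": self.gene_ids,
            "loadings": self.loadings.tolist(),
            "orientation_sign": self.orientation_sign,
            "pct_variance_pc1": self.pct_variance_pc1,
            "training_cohort_id": self.training_cohort_id,
            "training_score_median": self.training_score_median,
            "standardization": self.standardization.to_dict(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SignatureModel":
        d = json.loads(Path(path).read_text())
        return cls(
            platform=d["platform"],
            gene_ids=d["gene_ids"],
            loadings=np.asarray(d["loadings"]),
            orientation_sign=d["orientation_sign"],
            pct_variance_pc1=d["pct_variance_pc1"],
            training_cohort_id=d["training_cohort_id"],
            training_score_median=d["training_score_median"],
            standardization=StandardizationParams.from_dict(d["standardization"]),
        )


def train_signature(
    m: ExpressionMatrix, gene_ids: list[str], training_cohort_id: str = ""
) -> SignatureModel:
    """Fit PC1 loadings on a training cohort.

    Genes are z-scored within the cohort, the gene-gene covariance
    (equivalently, correlation) matrix is eigendecomposed, and the
    leading eigenvector — sign-flipped to non-negative mean — becomes
    the gene-weight vector.
    """
    if m.n_samples < 2:
        raise ValueError("training requires at least 2 samples")
    sub = m.subset_genes(gene_ids)
    z, params = standardize_genes(sub)

    zmat = z.values.to_numpy(dtype=float)
    cov = zmat @ zmat.T / (zmat.shape[1] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    v = evecs[:, order[0]]

    sign = -1 if v.mean() < 0 else 1
    v = sign * v

    total = evals.sum()
    if total <= 0:
        raise ValueError("degenerate training matrix: zero total variance")
    scores = v @ zmat

    return SignatureModel(
        platform=m.platform,
        gene_ids=list(gene_ids),
        loadings=v,
        orientation_sign=sign,
        pct_variance_pc1=float(evals[0] / total),
        training_cohort_id=training_cohort_id,
        training_score_median=float(np.median(scores)),
        standardization=params,
    )


def score_samples(
    model: SignatureModel, m: ExpressionMatrix, use_training_params: bool = False
) -> ScoreSet:
    """Project a cohort onto the trained loadings.

    By default each cohort is standardized against itself before the dot
    product; passing ``use_training_params=True`` applies the training
    cohort's gene means/SDs instead.  Labels are left unset.
    """
    missing = [g for g in model.gene_ids if g not in m.values.index]
    if missing:
        raise KeyError(f"signature genes absent from matrix: {missing}")
    sub = m.subset_genes(model.gene_ids)
    z, _ = standardize_genes(sub, model.standardization if use_training_params else None)
    scores = model.loadings @ z.values.to_numpy(dtype=float)
    return ScoreSet(scores=pd.Series(scores, index=z.sample_ids, name="score"))


def classify_by_percentile(scores: ScoreSet, percentile: float = 50.0) -> ScoreSet:
    """Label samples high/low at a percentile of their own score
    distribution (linear interpolation between order statistics).

    ``high`` means score strictly above the threshold; ties are low.
    """
    if len(scores.scores) < 2:
        raise ValueError("classification requires at least 2 samples")
    if not 0.0 < percentile < 100.0:
        raise ValueError("percentile must lie in (0, 100)")
    vals = scores.scores.to_numpy(dtype=float)
    threshold = float(np.percentile(vals, percentile))
    labels = pd.Series(np.where(vals > threshold, "high", "low"), index=scores.scores.index)
    return ScoreSet(
        scores=scores.scores.copy(),
        labels=labels,
        threshold_value=threshold,
        threshold_percentile=percentile,
    )


def cutoff_sweep(
    scores: ScoreSet,
    clinical: pd.DataFrame,
    percentiles: list[float] | None = None,
    endpoint: str = "os",
) -> pd.DataFrame:
    """Re-classify at each percentile and test low-vs-high survival.

    Returns one row per percentile with group sizes, the log-rank p and
    the unadjusted high-vs-low Cox hazard ratio.  Used to show the
    median threshold is not a knife-edge choice.
    """
    if percentiles is None:
        percentiles = list(range(25, 80, 5))
    clin = clinical.set_index("sample_id").loc[scores.sample_ids]
    rows = []
    for p in percentiles:
        labelled = classify_by_percentile(scores, p)
        labels = labelled.labels
        chi2, pval = _survival.logrank(clin.reset_index(), labels, endpoint=endpoint)
        try:
            hr, lo, hi, _ = _survival.cox_hr(clin.reset_index(), labels, endpoint=endpoint)
        except _survival.CoxConvergenceError:
            hr = lo = hi = np.nan
        rows.append(
            {
                "percentile": p,
                "n_low": int((labels == "low").sum()),
                "n_high": int((labels == "high").sum()),
                "logrank_chi2": chi2,
                "logrank_p": pval,
                "hr_high_vs_low": hr,
                "hr_ci_low": lo,
                "hr_ci_high": hi,
            }
        )
    return pd.DataFrame(rows)


def score_concordance(a: ScoreSet, b: ScoreSet) -> tuple[float, float]:
    """Pearson and Spearman correlation of two score sets over the same
    samples (e.g. FF vs FFPE scores of matched patients)."""
    if a.sample_ids != b.sample_ids:
        raise ValueError("score sets must cover the same samples in the same order")
    x = a.scores.to_numpy(dtype=float)
    y = b.scores.to_numpy(dtype=float)
    return float(stats.pearsonr(x, y).statistic), float(stats.spearmanr(x, y).statistic)
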