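"""Normalization, standardization and the cross-platform concordance filter.

NanoString-style count data are normalized by housekeeping (invariant
control) genes: each sample is scaled by the ratio of its control-gene
geometric mean to the cohort-level reference, then log2-transformed.
Gene-wise z-scoring puts cohorts measured on incompatible absolute scales
onto a common footing before PCA.  The concordance filter drops genes
whose paired FF/FFPE correlation falls below a threshold (0.5 by
convention), the screen that reduced a 106-gene candidate list to the
74-gene signature.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, PairedTissueSet


def housekeeping_normalize(m: ExpressionMatrix, control_gene_ids: list[str]) -> ExpressionMatrix:
    """Scale each sample by its control-gene geometric mean, then log2.

    The per-sample factor is the geometric mean of that sample's control
    counts divided by the geometric mean of those per-sample geometric
    means across the cohort, so a cohort with identical control profiles
    gets factors of exactly 1.  Output is ``log2(x + 1)``; control genes
    are retained.
    """
    if m.scale != "raw_counts":
        raise ValueError("housekeeping normalization expects a raw_counts matrix")
    missing = [g for g in control_gene_ids if g not in m.values.index]
    if missing:
        raise KeyError(f"control genes absent from matrix: {missing}")

    controls = m.values.loc[control_gene_ids].to_numpy(dtype=float)
    if (controls <= 0).all(axis=0).any():
        bad = [s for s, col in zip(m.sample_ids, controls.T) if (col <= 0).all()]
        raise ValueError(f"samples with no positive control counts: {bad}")

    # geometric means over strictly positive control counts
    logc = np.full(controls.shape, np.nan)
    np.log(controls, out=logc, where=controls > 0)
    sample_geomean = np.exp(np.nanmean(logc, axis=0))
    reference = np.exp(np.mean(np.log(sample_geomean)))
    factors = sample_geomean / reference

    normalized = m.values.to_numpy(dtype=float) / factors[None, :]
    out = pd.DataFrame(np.log2(normalized + 1.0), index=m.values.index, columns=m.values.columns)
    return ExpressionMatrix(out, platform=m.platform, scale="log2")


@dataclass
class StandardizationParams:
    """Per-gene mean and standard deviation used for z-scoring."""

    mean: pd.Series
    sd: pd.Series

    def __post_init__(self) -> None:
        if not self.mean.index.equals(self.sd.index):
            raise ValueError("mean and sd must share a gene index")
        if (self.sd <= 0).any():
            bad = list(self.sd.index[self.sd <= 0])
            raise ValueError(f"non-positive standard deviation for genes: {bad}")

    def to_dict(self) -> dict:
        return {
            "gene_ids": list(self.mean.index),
            "mean": self.mean.to_numpy().tolist(),
            "sd": self.sd.to_numpy().tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StandardizationParams":
        idx = pd.Index(d["gene_ids"])
        return cls(pd.Series(d["mean"], index=idx), pd.Series(d["sd"], index=idx))


def standardize_genes(
    m: ExpressionMatrix, params: StandardizationParams | None = None
) -> tuple[ExpressionMatrix, StandardizationParams]:
    """Z-score each gene; returns the standardized matrix and the
    parameters used.

    With ``params`` absent the per-gene mean and SD (ddof=1) are computed
    from ``m`` itself — the default, since cohorts on different platforms
    have incompatible absolute scales.  Supplying training-derived params
    applies them instead (sensitivity-analysis mode).
    """
    if params is None:
        mean = m.values.mean(axis=1)
        sd = m.values.std(axis=1, ddof=1)
        zero = sd.index[sd == 0].tolist()
        if zero:
            raise ValueError(f"zero-variance genes cannot be standardized: {zero}")
        params = StandardizationParams(mean, sd)
    else:
        missing = [g for g in m.gene_ids if g not in params.mean.index]
        if missing:
            raise KeyError(f"standardization params missing genes: {missing}")

    z = m.values.sub(params.mean.loc[m.values.index], axis=0).div(params.sd.loc[m.values.index], axis=0)
    return ExpressionMatrix(z, platform=m.platform, scale=m.scale), params


@dataclass
class ConcordanceReport:
    """Per-gene FF/FFPE correlations and the retain/remove decision."""

    table: pd.DataFrame  # columns: gene_id, pearson_r, spearman_r, retained
    threshold: float
    decisive_method: str

    @property
    def retained_genes(self) -> list[str]:
        return self.table.loc[self.table["retained"], "gene_id"].tolist()

    @property
    def removed_genes(self) -> list[str]:
        return self.table.loc[~self.table["retained"], "gene_id"].tolist()

    @property
    def n_retained(self) -> int:
        return int(self.table["retained"].sum())

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def concordance_filter(
    pair: PairedTissueSet, threshold: float = 0.5, method: str = "pearson"
) -> ConcordanceReport:
    """Correlate each gene's FF and FFPE profiles across paired samples
    and retain genes whose decisive correlation is >= ``threshold``.

    Both Pearson and Spearman correlations are reported; ``method``
    chooses which one decides removal (``both`` requires both to clear
    the threshold).  Genes exactly at the threshold are retained —
    removal applies to r strictly below it.
    """
    if method not in ("pearson", "spearman", "both"):
        raise ValueError(f"unknown decisive method {method!r}")
    n = pair.ff.n_samples
    if n < 3:
        raise ValueError(f"need at least 3 paired samples, got {n}")

    ff = pair.ff.values.to_numpy(dtype=float)
    ffpe = pair.ffpe.values.to_numpy(dtype=float)
    rows = []
    for gid, x, y in zip(pair.ff.gene_ids, ff, ffpe):
        pr = stats.pearsonr(x, y).statistic
        sr = stats.spearmanr(x, y).statistic
        if method == "pearson":
            decisive = pr
        elif method == "spearman":
            decisive = sr
        else:
            decisive = min(pr, sr)
        rows.append({"gene_id": gid, "pearson_r": pr, "spearman_r": sr, "retained": bool(decisive >= threshold)})

    return ConcordanceReport(pd.DataFrame(rows), threshold=threshold, decisive_method=method)
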