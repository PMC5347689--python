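"""Core data containers shared across the scoring pipeline.

Expression data travel as a gene-by-sample matrix tagged with platform
(fresh-frozen ``FF`` vs formalin-fixed ``FFPE``) and scale (``raw_counts``
for NanoString-style count data vs ``log2``).  Clinical data travel as a
plain :class:`pandas.DataFrame` with a fixed column contract (see
:data:`CLINICAL_COLUMNS`); helper functions validate and round-trip it
to/from CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

PLATFORMS = ("FF", "FFPE")
SCALES = ("raw_counts", "log2")

#: Required clinical-table columns.  ``arm`` is ``ACT`` (adjuvant
#: chemotherapy) or ``none``; stages follow the pooled I / II / III/IV
#: grouping used for stratified survival reporting.
CLINICAL_COLUMNS = [
    "sample_id",
    "cohort",
    "platform",
    "stage",
    "arm",
    "os_months",
    "os_event",
    "pfs_months",
    "pfs_event",
]

STAGES = ("I", "II", "III/IV", "unknown")
ENDPOINTS = ("os", "pfs")


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression values with platform and scale tags.

    ``values`` is a DataFrame indexed by gene id with one column per
    sample.  Raw-count matrices must be non-negative; all values must be
    finite and identifiers unique.
    """

    values: pd.DataFrame
    platform: str = "FF"
    scale: str = "log2"

    def __post_init__(self) -> None:
        if self.platform not in PLATFORMS:
            raise ValueError(f"unknown platform {self.platform!r}; expected one of {PLATFORMS}")
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        arr = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("expression values must be finite")
        if self.scale == "raw_counts" and (arr < 0).any():
            raise ValueError("raw count values must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        gene_ids = list(gene_ids)
        missing = [g for g in gene_ids if g not in self.values.index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing}")
        return ExpressionMatrix(self.values.loc[gene_ids].copy(), self.platform, self.scale)

    def to_tsv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, platform: str = "FF", scale: str = "log2") -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df, platform=platform, scale=scale)


@dataclass
class PairedTissueSet:
    """Matched FF/FFPE measurements of the same genes in the same patients."""

    ff: ExpressionMatrix
    ffpe: ExpressionMatrix

    def __post_init__(self) -> None:
        if self.ff.gene_ids != self.ffpe.gene_ids:
            raise ValueError("paired matrices must share gene ids in the same order")
        if self.ff.sample_ids != self.ffpe.sample_ids:
            raise ValueError("paired matrices must share sample ids in the same order")


def validate_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    """Check the clinical-table column contract and basic invariants."""
    missing = [c for c in CLINICAL_COLUMNS if c not in clinical.columns]
    if missing:
        raise ValueError(f"clinical table missing columns: {missing}")
    if clinical["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in clinical table")
    for col in ("os_months", "pfs_months"):
        if (clinical[col] <= 0).any():
            raise ValueError(f"{col} must be positive")
    for col in ("os_event", "pfs_event"):
        if not clinical[col].isin([0, 1]).all():
            raise ValueError(f"{col} must be 0/1")
    bad = set(clinical["stage"]) - set(STAGES)
    if bad:
        raise ValueError(f"unknown stage values: {sorted(bad)}")
    return clinical


def write_clinical(clinical: pd.DataFrame, path: str | Path) -> None:
    clinical.to_csv(path, index=False)


def read_clinical(path: str | Path) -> pd.DataFrame:
    return validate_clinical(pd.read_csv(path))


@dataclass
class ScoreSet:
    """Continuous E2F scores with optional low/high labels.

    A sample is labelled ``high`` iff its score strictly exceeds the
    threshold; ties go to ``low`` (conservative toward recommending
    treatment).  ``threshold_percentile`` records which percentile of the
    classified distribution the threshold came from.
    """

    scores: pd.Series  # index = sample ids
    labels: pd.Series | None = None
    threshold_value: float | None = None
    threshold_percentile: float | None = None

    def __post_init__(self) -> None:
        if self.scores.index.has_duplicates:
            raise ValueError("duplicate sample ids in score set")
        if self.labels is not None:
            if not self.labels.index.equals(self.scores.index):
                raise ValueError("labels must be indexed like scores")
            expected = np.where(self.scores.to_numpy() > self.threshold_value, "high", "low")
            if not (self.labels.to_numpy() == expected).all():
                raise ValueError("labels inconsistent with threshold rule (high iff score > threshold)")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.index)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"sample_id": self.scores.index, "score": self.scores.to_numpy()})
        df["label"] = self.labels.to_numpy() if self.labels is not None else ""
        df["threshold_value"] = self.threshold_value if self.threshold_value is not None else np.nan
        df["threshold_percentile"] = (
            self.threshold_percentile if self.threshold_percentile is not None else np.nan
        )
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)
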