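"""Count-matrix handling and case-vs-control gene activity.

This module owns the raw/normalized/TPM representation of a genes x samples
expression matrix, the median-of-ratios size-factor normalization (with a
pseudo-count added after division), and the per-gene statistics computed for a
single tumor sample against a panel of control profiles:

* CNR - case-to-normal ratio: sample value over the geometric mean of the
  control panel.
* BTIF - beyond-tolerance-interval flag: 1 when the sample's log expression
  deviates significantly from the control panel (default: two-sided z test at
  ``alpha``).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

STAGES = ("raw", "normalized", "tpm")

__all__ = [
    "ExpressionMatrix",
    "GeneActivityVector",
    "NormalizationError",
    "normalize_median_of_ratios",
    "compute_tpm",
    "compute_cnr",
    "compute_btif",
    "compute_activity",
    "geometric_mean",
]


class NormalizationError(ValueError):
    """Raised when size factors cannot be estimated."""


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of non-negative expression values.

    ``stage`` tracks provenance; downstream operations gate on it so raw
    counts cannot be normalized twice or fed where normalized values are
    expected.
    """

    values: pd.DataFrame
    stage: str = "raw"

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        arr = self.values.to_numpy(dtype=float)
        if arr.size and np.nanmin(arr) < 0:
            raise ValueError("expression values must be non-negative")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def sample(self, sample_id: str) -> pd.Series:
        return self.values[sample_id]

    @classmethod
    def read_tsv(cls, path, stage: str = "raw") -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.index.name = None
        df.columns = df.columns.astype(str)
        return cls(df, stage=stage)

    def write_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id")


@dataclass
class GeneActivityVector:
    """Per-gene CNR and BTIF of one tumor sample vs the control panel."""

    gene_ids: pd.Index
    cnr: np.ndarray
    btif: np.ndarray
    sample_id: str | None = None

    def __post_init__(self) -> None:
        self.cnr = np.asarray(self.cnr, dtype=float)
        self.btif = np.asarray(self.btif, dtype=int)
        if not (len(self.gene_ids) == len(self.cnr) == len(self.btif)):
            raise ValueError("gene_ids, cnr and btif must have equal length")
        if np.any(self.cnr <= 0):
            raise ValueError("CNR values must be strictly positive")
        if not np.isin(self.btif, (0, 1)).all():
            raise ValueError("BTIF values must be 0 or 1")

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cnr": self.cnr, "btif": self.btif}, index=self.gene_ids)


def geometric_mean(values: np.ndarray, axis: int = 0) -> np.ndarray:
    """Geometric mean computed in log space for numerical stability."""
    values = np.asarray(values, dtype=float)
    if np.any(values <= 0):
        raise ValueError("geometric mean requires strictly positive values")
    return np.exp(np.mean(np.log(values), axis=axis))


def normalize_median_of_ratios(
    counts: ExpressionMatrix, pseudocount: float = 1.0
) -> tuple[ExpressionMatrix, pd.Series]:
    """Median-of-ratios size-factor normalization of a raw count matrix.

    The size factor of sample ``j`` is the median, over genes with strictly
    positive counts in every sample, of ``counts[g, j] / geomean_g``.  Counts
    are divided by their sample's size factor and the pseudo-count is added
    afterwards.

    Returns the normalized matrix (stage ``normalized``) and the per-sample
    size factors.
    """
    if counts.stage != "raw":
        raise NormalizationError(
            f"normalization requires raw counts, got stage {counts.stage!r}"
        )
    mat = counts.values.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise NormalizationError("no gene has positive counts in every sample")
    logs = np.log(mat[positive])
    log_geomeans = logs.mean(axis=1)
    ratios = logs - log_geomeans[:, None]
    size_factors = np.exp(np.median(ratios, axis=0))
    normalized = mat / size_factors[None, :] + pseudocount
    out = ExpressionMatrix(
        pd.DataFrame(normalized, index=counts.gene_ids, columns=counts.sample_ids),
        stage="normalized",
    )
    return out, pd.Series(size_factors, index=counts.sample_ids, name="size_factor")


def compute_tpm(
    counts: ExpressionMatrix, gene_lengths: Mapping[str, float]
) -> ExpressionMatrix:
    """Transcripts-per-million from raw counts and gene lengths in base pairs.

    Every non-degenerate column sums to 1e6.  All-zero columns are emitted as
    zeros with a warning rather than erroring, since degenerate simulated
    inputs can produce them.
    """
    if counts.stage != "raw":
        raise ValueError(f"TPM requires raw counts, got stage {counts.stage!r}")
    lengths = np.empty(len(counts.gene_ids))
    for i, gene in enumerate(counts.gene_ids):
        if gene not in gene_lengths:
            raise KeyError(f"missing gene length for {gene!r}")
        length = float(gene_lengths[gene])
        if length <= 0:
            raise ValueError(f"non-positive length for gene {gene!r}")
        lengths[i] = length
    rates = counts.values.to_numpy(dtype=float) / lengths[:, None]
    colsums = rates.sum(axis=0)
    zero_cols = colsums == 0
    if zero_cols.any():
        bad = list(counts.sample_ids[zero_cols])
        warnings.warn(f"all-zero TPM column(s): {bad}", stacklevel=2)
        colsums = np.where(zero_cols, 1.0, colsums)
    tpm = rates / colsums[None, :] * 1e6
    return ExpressionMatrix(
        pd.DataFrame(tpm, index=counts.gene_ids, columns=counts.sample_ids),
        stage="tpm",
    )


def _check_case_control(sample: pd.Series, controls: ExpressionMatrix) -> None:
    if controls.shape[1] < 2:
        raise ValueError("control panel must contain at least 2 samples")
    if not sample.index.equals(controls.gene_ids):
        raise ValueError("sample and control panel must share the same gene ids")
    if (sample <= 0).any() or (controls.values <= 0).to_numpy().any():
        raise ValueError(
            "case/control values must be strictly positive (pseudo-count missing?)"
        )


def compute_cnr(sample: pd.Series, controls: ExpressionMatrix) -> pd.Series:
    """Case-to-normal ratio: sample / geometric mean of the control panel."""
    _check_case_control(sample, controls)
    geo = geometric_mean(controls.values.to_numpy(dtype=float), axis=1)
    return pd.Series(sample.to_numpy(dtype=float) / geo, index=sample.index, name="cnr")


def _btif_zscore(
    log_sample: np.ndarray, log_controls: np.ndarray, alpha: float
) -> np.ndarray:
    mean = log_controls.mean(axis=1)
    sd = log_controls.std(axis=1, ddof=1)
    diff = log_sample - mean
    flags = np.zeros(len(log_sample), dtype=int)
    degenerate = sd == 0
    # a panel with zero spread flags any deviation at all
    flags[degenerate] = (diff[degenerate] != 0).astype(int)
    ok = ~degenerate
    pvals = 2.0 * stats.norm.sf(np.abs(diff[ok]) / sd[ok])
    flags[ok] = (pvals <= alpha).astype(int)
    return flags


def _btif_quantile(
    log_sample: np.ndarray, log_controls: np.ndarray, alpha: float
) -> np.ndarray:
    lo = np.quantile(log_controls, alpha / 2.0, axis=1)
    hi = np.quantile(log_controls, 1.0 - alpha / 2.0, axis=1)
    return ((log_sample < lo) | (log_sample > hi)).astype(int)


_BTIF_METHODS: dict[str, Callable[[np.ndarray, np.ndarray, float], np.ndarray]] = {
    "zscore": _btif_zscore,
    "quantile": _btif_quantile,
}


def compute_btif(
    sample: pd.Series,
    controls: ExpressionMatrix,
    alpha: float = 0.05,
    method: str | Callable = "zscore",
) -> pd.Series:
    """Beyond-tolerance-interval flag per gene.

    With the default ``zscore`` strategy a gene is flagged when the sample's
    log value falls outside the two-sided ``1 - alpha`` band implied by the
    control panel's log mean and SD.  ``method`` may also be a callable
    ``f(log_sample, log_controls, alpha) -> flags`` so rank-based variants can
    be plugged in.
    """
    _check_case_control(sample, controls)
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    fn = _BTIF_METHODS[method] if isinstance(method, str) else method
    log_sample = np.log(sample.to_numpy(dtype=float))
    log_controls = np.log(controls.values.to_numpy(dtype=float))
    flags = fn(log_sample, log_controls, alpha)
    return pd.Series(np.asarray(flags, dtype=int), index=sample.index, name="btif")


def compute_activity(
    sample: pd.Series,
    controls: ExpressionMatrix,
    alpha: float = 0.05,
    method: str | Callable = "zscore",
    sample_id: str | None = None,
) -> GeneActivityVector:
    """CNR and BTIF of one normalized sample against the control panel."""
    cnr = compute_cnr(sample, controls)
    btif = compute_btif(sample, controls, alpha=alpha, method=method)
    return GeneActivityVector(
        gene_ids=sample.index,
        cnr=cnr.to_numpy(),
        btif=btif.to_numpy(),
        sample_id=sample_id if sample_id is not None else getattr(sample, "name", None),
    )


def read_gene_lengths(path) -> dict[str, float]:
    """2-column TSV (gene id, length in bp) -> mapping."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "length"])
    return dict(zip(df["gene_id"].astype(str), df["length"].astype(float)))
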