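"""Expression-matrix I/O, low-expression filtering, log transform and the
mean-variance diagnostic.

The expression container tracks its scale explicitly: raw FPKM (``"fpkm"``)
or log2(FPKM + 1) (``"log2p1"``).  Operations that are only meaningful on one
scale guard on the tag, so the filter cannot silently run on logged values
and the transform cannot be applied twice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SCALE_FPKM = "fpkm"
SCALE_LOG2P1 = "log2p1"

#: Default low-expression cutoff: drop genes whose maximum FPKM over all
#: samples is strictly below this value.
DEFAULT_MIN_MAX_FPKM = 20.0


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with an explicit scale tag.

    Parameters
    ----------
    data
        DataFrame indexed by gene id, columns are sample ids.  Values must be
        finite and non-negative on either scale.
    scale
        ``"fpkm"`` for raw FPKM values, ``"log2p1"`` after log2(x+1).
    """

    data: pd.DataFrame
    scale: str = SCALE_FPKM

    def __post_init__(self) -> None:
        if self.scale not in (SCALE_FPKM, SCALE_LOG2P1):
            raise ValueError(f"unknown scale tag {self.scale!r}")
        idx = self.data.index
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise ValueError(f"duplicate gene id {dup!r}")
        cols = self.data.columns
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("non-numeric expression values")
        if not np.all(np.isfinite(values)):
            r, c = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite value at gene {idx[r]!r}, sample {cols[c]!r}"
            )
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative value at gene {idx[r]!r}, sample {cols[c]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class MeanVarianceProfile:
    """Per-gene mean/SD with genes ranked by mean, plus a running-median SD
    trend over rank windows (the classic RNA-seq mean-variance diagnostic)."""

    table: pd.DataFrame  # columns: gene, rank, mean, sd, trend
    window: int = 301

    def spearman_mean_sd(self) -> float:
        """Spearman rank correlation between gene means and gene SDs."""
        from scipy.stats import spearmanr

        rho, _ = spearmanr(self.table["mean"], self.table["sd"])
        return float(rho)


def read_expression_matrix(path) -> ExpressionMatrix:
    """Read a TSV with a header row of sample ids and first column of gene
    ids into an :class:`ExpressionMatrix` tagged as raw FPKM."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    bad = [c for c in frame.columns if not np.issubdtype(frame[c].dtype, np.number)]
    if bad:
        col = bad[0]
        row = frame.index[pd.to_numeric(frame[col], errors="coerce").isna()][0]
        raise ValueError(f"non-numeric cell at gene {row!r}, sample {col!r}")
    return ExpressionMatrix(frame.astype(float), scale=SCALE_FPKM)


def write_expression_matrix(m: ExpressionMatrix, path) -> None:
    m.data.to_csv(path, sep="\t", index_label="gene")


def filter_low_expression(
    m: ExpressionMatrix, min_max_fpkm: float = DEFAULT_MIN_MAX_FPKM
) -> ExpressionMatrix:
    """Drop genes whose maximum FPKM across samples is strictly below
    ``min_max_fpkm``; gene order is preserved.

    Only defined on the raw FPKM scale.
    """
    if m.scale != SCALE_FPKM:
        raise ValueError("filter_low_expression requires the raw FPKM scale")
    keep = m.data.max(axis=1) >= min_max_fpkm
    kept = m.data.loc[keep]
    if kept.shape[0] == 0:
        logger.warning("low-expression filter removed every gene")
    else:
        logger.info(
            "low-expression filter kept %d of %d genes (max FPKM >= %g)",
            kept.shape[0], m.n_genes, min_max_fpkm,
        )
    return ExpressionMatrix(kept.copy(), scale=SCALE_FPKM)


def log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Apply log2(x + 1); retags the matrix so it cannot be applied twice."""
    if m.scale != SCALE_FPKM:
        raise ValueError("matrix already log-transformed (scale tag log2p1)")
    return ExpressionMatrix(np.log2(m.data + 1.0), scale=SCALE_LOG2P1)


def inverse_log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Exact inverse of :func:`log_transform`: 2**y - 1."""
    if m.scale != SCALE_LOG2P1:
        raise ValueError("matrix is not on the log2p1 scale")
    return ExpressionMatrix(2.0 ** m.data - 1.0, scale=SCALE_FPKM)


def mean_variance_profile(m: ExpressionMatrix, window: int = 301) -> MeanVarianceProfile:
    """Per-gene mean and sample SD (n-1 denominator), genes ranked by mean
    ascending (ties broken by gene id), with a running median of SD over a
    centered window of ``window`` ranks, clipped at the boundaries."""
    if m.n_samples < 2:
        raise ValueError("mean_variance_profile needs at least 2 samples")
    means = m.data.mean(axis=1)
    sds = m.data.std(axis=1, ddof=1)
    order = sorted(m.gene_ids, key=lambda g: (means[g], g))
    table = pd.DataFrame(
        {
            "gene": order,
            "rank": np.arange(1, len(order) + 1),
            "mean": means.loc[order].to_numpy(),
            "sd": sds.loc[order].to_numpy(),
        }
    )
    table["trend"] = (
        table["sd"].rolling(window, center=True, min_periods=1).median()
    )
    return MeanVarianceProfile(table, window=window)


def write_mean_variance_profile(p: MeanVarianceProfile, path) -> None:
    p.table.to_csv(path, sep="\t", index=False)
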