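"""Pairwise Pearson correlation QC between samples, with grouped summaries.

Correlations are computed over genes for every sample pair (within a
platform/phase, or across platforms after harmonization) and summarized per
group as mean r with a 95% t-interval on the raw r values, clipped to
[-1, 1] (a single value yields a degenerate point interval).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ExpressionMatrix

_CORR_UNITS = ("log2epm1", "rle")


def _columns_standardized(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    X = df.to_numpy(dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    flat = sd == 0
    sd_safe = np.where(flat, 1.0, sd)
    return (X - mu) / sd_safe, flat


def pearson_matrix(a, b=None) -> pd.DataFrame:
    """Pearson r over genes for every pair of samples of ``a`` x ``b``.

    ``a`` and ``b`` are ExpressionMatrix (log2 or RLE units, same unit, same
    gene order) or plain DataFrames.  With ``b=None`` the symmetric
    within-``a`` matrix is returned.  Zero-variance samples yield NaN rows /
    columns (flagged as undefined rather than raising).
    """
    if b is None:
        b = a
    if isinstance(a, ExpressionMatrix) or isinstance(b, ExpressionMatrix):
        if not (isinstance(a, ExpressionMatrix) and isinstance(b, ExpressionMatrix)):
            raise TypeError("mixed ExpressionMatrix / DataFrame input")
        if a.unit != b.unit:
            raise ValueError(f"unit mismatch: {a.unit!r} vs {b.unit!r}")
        if a.unit not in _CORR_UNITS:
            raise ValueError(f"correlations expect units in {_CORR_UNITS}, got {a.unit!r}")
        da, db = a.data, b.data
    else:
        da, db = pd.DataFrame(a), pd.DataFrame(b)
    if not da.index.equals(db.index):
        raise ValueError("gene sets/order differ between the two matrices")
    n = len(da)
    if n < 2:
        raise ValueError("need at least 2 genes")
    Za, flat_a = _columns_standardized(da)
    Zb, flat_b = _columns_standardized(db)
    R = (Za.T @ Zb) / (n - 1)
    R = np.clip(R, -1.0, 1.0)
    R[flat_a, :] = np.nan
    R[:, flat_b] = np.nan
    return pd.DataFrame(R, index=da.columns, columns=db.columns)


@dataclass
class CorrelationSummary:
    """Mean Pearson r over a group of sample pairs with a 95% t-interval."""

    group: str
    n: int
    mean: float
    ci_low: float
    ci_high: float
    values: list[float] = field(default_factory=list)

    def as_row(self) -> dict:
        return {
            "group": self.group,
            "n_pairs": self.n,
            "mean_r": self.mean,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
        }


def summarize_correlations(values, group: str = "all") -> CorrelationSummary:
    """Mean and 95% CI (t-interval, clipped to [-1, 1]) of a set of r values."""
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError(f"no finite correlation values in group {group!r}")
    mean = float(vals.mean())
    if vals.size == 1:
        lo = hi = mean
    else:
        sd = vals.std(ddof=1)
        half = stats.t.ppf(0.975, vals.size - 1) * sd / np.sqrt(vals.size)
        lo, hi = max(mean - half, -1.0), min(mean + half, 1.0)
    return CorrelationSummary(group, int(vals.size), mean, lo, hi, vals.tolist())


def matched_pair_values(
    corr: pd.DataFrame, cells_a: pd.Series, cells_b: pd.Series
) -> dict[str, np.ndarray]:
    """Split a cross-platform correlation matrix by cell-line match.

    ``cells_a`` / ``cells_b`` map the matrix rows / columns to cell-line
    labels.  Matching pairs share the label; non-matching pairs are all
    other (off-diagonal) pairs.
    """
    ca = cells_a.loc[corr.index].to_numpy()
    cb = cells_b.loc[corr.columns].to_numpy()
    match = ca[:, None] == cb[None, :]
    vals = corr.to_numpy()
    return {
        "matching": vals[match],
        "non_matching": vals[~match],
    }


def replicate_pair_values(corr: pd.DataFrame, cells: pd.Series) -> np.ndarray:
    """Upper-triangle correlations between replicates of the same cell line."""
    c = cells.loc[corr.index].to_numpy()
    same = c[:, None] == c[None, :]
    iu = np.triu(np.ones(corr.shape, dtype=bool), k=1)
    return corr.to_numpy()[same & iu]
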