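"""Relative log expression (RLE) platform correction.

Here RLE is a *ratio*, not the conventional subtract-the-median log
difference: for gene g in cell line c within one platform,

    RLE(g, c) = log2(EPM(g, c) + 1) / mean_c' log2(EPM(g, c') + 1)

The denominator is the gene's average log2 expression across all cell lines
of the *same* platform, so a per-gene platform-specific scale factor cancels
identically and cell-line structure is preserved.  Genes whose log2 values
are all zero across cell lines (0/0) map to the neutral value 1.0 and are
flagged, keeping the gene universe intact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix
from .correlation import pearson_matrix
from .ordination import euclidean_distance, pca
from .permanova import DispersionTest, Permanova


@dataclass
class RleMatrix:
    """RLE ratios (genes x cell lines) for one platform."""

    matrix: ExpressionMatrix       # unit tag 'rle'
    denominator: pd.Series         # per-gene cross-cell-line mean log2(EPM+1)
    flagged_genes: pd.Index        # genes with zero denominator (set to 1.0)
    platform: str | None = None


def rle_normalize(
    m: ExpressionMatrix,
    platform: str | None = None,
    denominator: str = "log2",
) -> RleMatrix:
    """RLE-normalize one platform's log2(EPM+1) matrix.

    ``denominator='log2'`` (default) divides by the per-gene mean of the
    log2 values; ``denominator='epm1'`` divides by the per-gene mean of
    (EPM + 1) instead — an auditing variant, since the two readings of the
    defining ratio differ and only the log2 reading cancels platform scale
    factors on the log scale.
    """
    if m.unit != "log2epm1":
        raise ValueError(f"rle_normalize expects log2(EPM+1) input, got {m.unit!r}")
    if m.data.shape[1] < 2:
        raise ValueError("RLE needs at least 2 cell lines (denominator degenerates)")
    if denominator == "log2":
        den = m.data.mean(axis=1)
    elif denominator == "epm1":
        den = np.exp2(m.data).mean(axis=1)  # mean of EPM + 1
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    flagged = m.gene_ids[den == 0]
    den_safe = den.replace(0, np.nan)
    out = m.data.div(den_safe, axis=0)
    out.loc[flagged] = 1.0
    return RleMatrix(m.with_data(out, "rle"), den, flagged, platform)


@dataclass
class RleRerun:
    """The log2-stage analysis surface repeated on RLE values."""

    pca: object
    permanova: object
    dispersion: object
    correlations: pd.DataFrame      # cross-platform sample correlations

    def summary(self) -> str:
        return (
            "RLE rerun\n"
            f"  platform R2: {self.permanova.r2('platform'):0.4f}"
            f" (p={self.permanova.p('platform'):0.4g})\n"
            f"  dispersion: F={self.dispersion.F:0.4g}, p={self.dispersion.p:0.4g}"
        )


def rle_pipeline_rerun(
    t: RleMatrix,
    r: RleMatrix,
    n_perm: int = 999,
    seed: int | None = None,
    dispersion_center: str = "centroid",
) -> RleRerun:
    """Repeat PCA, PERMANOVA (~platform), dispersion test and cross-platform
    correlations on RLE-normalized matrices from the two platforms."""
    for x in (t, r):
        if x.matrix.unit != "rle":
            raise ValueError(f"expected RLE input, got unit {x.matrix.unit!r}")
    if not t.matrix.gene_ids.equals(r.matrix.gene_ids):
        raise ValueError("gene sets/order differ between platforms")
    X = pd.concat([t.matrix.data.T, r.matrix.data.T])
    X.index = [f"T_{c}" for c in t.matrix.sample_ids] + [
        f"R_{c}" for c in r.matrix.sample_ids
    ]
    factors = pd.DataFrame(
        {
            "platform": ["TARGETED"] * t.matrix.data.shape[1]
            + ["REFERENCE"] * r.matrix.data.shape[1]
        },
        index=X.index,
    )
    ord_res = pca(X)
    D = euclidean_distance(X)
    perm = Permanova(D, factors, ["platform"]).fit(n_perm=n_perm, seed=seed)
    disp = DispersionTest(D, factors["platform"], dispersion_center).fit()
    corr = pearson_matrix(t.matrix, r.matrix)
    return RleRerun(ord_res, perm, disp, corr)
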