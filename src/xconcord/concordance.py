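"""Per-gene cross-platform difference statistics and the stepwise
non-concordant-gene determination.

The central quantity is the per-gene, per-cell-line difference

    Δ(g, c) = log2(EPM_targeted + 1) − log2(EPM_reference + 1)

computed on replicate-averaged, harmonized matrices.  Genes are classified
by iterating symmetric percentile pairs — (10, 90), (11, 89), … — of the Δ
distribution: at each step, per-cell-line percentiles are averaged across
cell lines into a cutoff pair (lo, hi); expressed genes (cross-cell-line
average EPM ≥ 5 on either platform) whose mean Δ falls strictly outside
[lo, hi] are removed, and a PERMANOVA of Euclidean distances on the
remaining genes measures how much variance the platform factor still
explains.  The loop stops at the first pair with platform R² below the
target (default 10%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ExpressionMatrix
from .ordination import euclidean_distance
from .permanova import Permanova, VarianceAttribution


@dataclass
class DiffProfile:
    """Distribution of cross-platform log2 differences Δ(g, c)."""

    delta: pd.DataFrame            # genes x cell lines
    per_cell_line: pd.DataFrame    # q1, median, q3, iqr per cell line
    gene_mean: pd.Series           # mean Δ per gene across cell lines
    gene_mean_abs: pd.Series       # mean |Δ| per gene

    def cell_lines_by_iqr(self) -> pd.Index:
        """Cell lines ordered from narrowest to widest IQR of Δ."""
        return self.per_cell_line["iqr"].sort_values().index


def _check_pair(t: ExpressionMatrix, r: ExpressionMatrix, unit: str) -> None:
    if t.unit != unit or r.unit != unit:
        raise ValueError(f"expected unit {unit!r}, got {t.unit!r} / {r.unit!r}")
    if t.data.shape != r.data.shape:
        raise ValueError("matrices have different shapes")
    if not t.gene_ids.equals(r.gene_ids):
        raise ValueError("gene sets/order differ between platforms")


def diff_profile(t: ExpressionMatrix, r: ExpressionMatrix) -> DiffProfile:
    """Δ = targeted − reference in log2(EPM+1) with per-cell-line quartiles.

    Quartiles use linear-interpolation quantiles; each matrix column is one
    cell line (replicate-averaged), columns aligned by position.
    """
    _check_pair(t, r, "log2epm1")
    delta = pd.DataFrame(
        t.data.to_numpy() - r.data.to_numpy(),
        index=t.gene_ids,
        columns=[str(c) for c in t.sample_ids],
    )
    q = delta.quantile([0.25, 0.5, 0.75], interpolation="linear")
    per_cl = pd.DataFrame(
        {
            "q1": q.loc[0.25],
            "median": q.loc[0.5],
            "q3": q.loc[0.75],
        }
    )
    per_cl["iqr"] = per_cl["q3"] - per_cl["q1"]
    return DiffProfile(delta, per_cl, delta.mean(axis=1), delta.abs().mean(axis=1))


def average_median_diff(dp: DiffProfile) -> float:
    """Mean over cell lines of the per-cell-line median Δ."""
    return float(dp.per_cell_line["median"].mean())


def expression_gate(
    t_epm: ExpressionMatrix, r_epm: ExpressionMatrix, threshold: float = 5.0
) -> pd.Series:
    """Expressed-gene mask: cross-cell-line average EPM ≥ threshold on either
    platform (and/or semantics).  Genes failing the gate are 'effectively
    concordant' — both platforms agree they are not expressed."""
    _check_pair(t_epm, r_epm, "epm")
    return (t_epm.data.mean(axis=1) >= threshold) | (r_epm.data.mean(axis=1) >= threshold)


def percentile_cutoffs(
    dp: DiffProfile,
    p_low: float,
    p_high: float,
    scope: str = "all_genes",
    gate: pd.Series | None = None,
) -> tuple[float, float]:
    """Cutoff pair: per-cell-line Δ percentiles averaged across cell lines.

    ``scope`` selects the genes entering the percentile computation:
    ``all_genes`` (default, matches the ~20% tail arithmetic of the boxplot
    distributions) or ``gated_genes`` (expressed genes only; needs ``gate``).
    """
    if not (0 < p_low < p_high < 100):
        raise ValueError(f"need 0 < p_low < p_high < 100, got {(p_low, p_high)}")
    if scope == "all_genes":
        delta = dp.delta
    elif scope == "gated_genes":
        if gate is None:
            raise ValueError("scope='gated_genes' requires a gate mask")
        delta = dp.delta.loc[gate.reindex(dp.delta.index, fill_value=False)]
    else:
        raise ValueError(f"unknown scope {scope!r}")
    lo = delta.quantile(p_low / 100.0, interpolation="linear").mean()
    hi = delta.quantile(p_high / 100.0, interpolation="linear").mean()
    return float(lo), float(hi)


CATEGORIES = (
    "concordant_expressed",
    "concordant_low_expression",
    "nonconcordant_high_targeted",
    "nonconcordant_high_reference",
)


class ConcordanceError(RuntimeError):
    """Raised when no percentile pair meets the platform-variance target."""

    def __init__(self, message: str, trace: pd.DataFrame):
        super().__init__(message)
        self.trace = trace


@dataclass
class ConcordanceResults:
    """Outcome of the stepwise non-concordant-gene determination."""

    classification: pd.Series          # per-gene category
    cutoffs: tuple[float, float]       # (lo, hi) in log2 units
    percentiles: tuple[float, float]   # final (p_low, p_high)
    trace: pd.DataFrame                # one row per percentile pair tried
    diff: DiffProfile
    gate: pd.Series
    platform_permanova: VarianceAttribution   # on the retained genes
    gate_threshold: float

    @property
    def nonconcordant_genes(self) -> pd.Index:
        return self.classification.index[
            self.classification.str.startswith("nonconcordant")
        ]

    @property
    def concordant_expressed_genes(self) -> pd.Index:
        return self.classification.index[self.classification == "concordant_expressed"]

    def counts(self) -> pd.Series:
        return self.classification.value_counts().reindex(CATEGORIES, fill_value=0)

    def summary(self) -> str:
        c = self.counts()
        lines = [
            "Non-concordant gene determination",
            f"  terminated at percentiles ({self.percentiles[0]:g}, {self.percentiles[1]:g})"
            f" after {len(self.trace)} step(s)",
            f"  cutoffs: lo={self.cutoffs[0]:0.3f}, hi={self.cutoffs[1]:0.3f} log2(EPM+1)",
            f"  expression gate: mean EPM >= {self.gate_threshold:g}"
            f" on either platform ({int(self.gate.sum())} of {len(self.gate)} genes pass)",
            f"  platform R2 on retained genes: "
            f"{self.platform_permanova.r2('platform'):0.4f}",
            "  classification:",
        ]
        for cat in CATEGORIES:
            lines.append(f"    {cat}: {int(c[cat])}")
        return "\n".join(lines)


class ConcordanceModel:
    """Stepwise determination of cross-platform non-concordant genes.

    Parameters
    ----------
    t_log2, r_log2 :
        Harmonized log2(EPM+1) matrices (genes x cell lines, replicate-
        averaged, identical gene order; one column per cell line).
    t_epm, r_epm :
        The matching EPM matrices, used only for the expression gate.
    gate_threshold :
        Minimum cross-cell-line average EPM on either platform for a gene to
        count as expressed (default 5).
    scope :
        Gene scope of the percentile computation (``all_genes`` default).
    """

    def __init__(
        self,
        t_log2: ExpressionMatrix,
        r_log2: ExpressionMatrix,
        t_epm: ExpressionMatrix,
        r_epm: ExpressionMatrix,
        gate_threshold: float = 5.0,
        scope: str = "all_genes",
    ):
        _check_pair(t_log2, r_log2, "log2epm1")
        _check_pair(t_epm, r_epm, "epm")
        if not t_log2.gene_ids.equals(t_epm.gene_ids):
            raise ValueError("log2 and EPM matrices have different gene sets")
        self.t_log2, self.r_log2 = t_log2, r_log2
        self.diff = diff_profile(t_log2, r_log2)
        self.gate = expression_gate(t_epm, r_epm, gate_threshold)
        self.gate_threshold = gate_threshold
        self.scope = scope

    def _platform_r2(self, keep: pd.Index, n_perm: int, seed) -> VarianceAttribution:
        X = pd.concat(
            [self.t_log2.data.loc[keep].T, self.r_log2.data.loc[keep].T]
        )
        X.index = [f"T_{c}" for c in self.t_log2.sample_ids] + [
            f"R_{c}" for c in self.r_log2.sample_ids
        ]
        factors = pd.DataFrame(
            {"platform": ["TARGETED"] * self.t_log2.data.shape[1]
             + ["REFERENCE"] * self.r_log2.data.shape[1]},
            index=X.index,
        )
        D = euclidean_distance(X)
        return Permanova(D, factors, ["platform"]).fit(n_perm=n_perm, seed=seed)

    def fit(
        self,
        start: tuple[float, float] = (10.0, 90.0),
        step: float = 1.0,
        r2_target: float = 0.10,
        n_perm: int = 999,
        seed: int | None = None,
    ) -> ConcordanceResults:
        """Iterate percentile pairs until platform R² drops below target.

        Inside the loop the PERMANOVA R² is computed without permutations
        (it is permutation-free); the final retained-gene model is refitted
        with ``n_perm`` permutations for the reported p-value.
        """
        p_low, p_high = start
        rows = []
        genes = self.diff.delta.index
        while p_low <= 49.0 and p_low < p_high:
            lo, hi = percentile_cutoffs(self.diff, p_low, p_high, self.scope, self.gate)
            outside = (self.diff.gene_mean < lo) | (self.diff.gene_mean > hi)
            removed = self.gate & outside
            keep = genes[~removed]
            att = self._platform_r2(keep, n_perm=0, seed=None)
            r2 = att.r2("platform")
            rows.append(
                {
                    "p_low": p_low,
                    "p_high": p_high,
                    "cutoff_lo": lo,
                    "cutoff_hi": hi,
                    "n_removed": int(removed.sum()),
                    "platform_r2": r2,
                }
            )
            if r2 < r2_target:
                final = self._platform_r2(keep, n_perm=n_perm, seed=seed)
                classification = pd.Series("concordant_expressed", index=genes)
                classification[~self.gate] = "concordant_low_expression"
                classification[removed & (self.diff.gene_mean > hi)] = (
                    "nonconcordant_high_targeted"
                )
                classification[removed & (self.diff.gene_mean < lo)] = (
                    "nonconcordant_high_reference"
                )
                return ConcordanceResults(
                    classification,
                    (lo, hi),
                    (p_low, p_high),
                    pd.DataFrame(rows),
                    self.diff,
                    self.gate,
                    final,
                    self.gate_threshold,
                )
            p_low += step
            p_high -= step
        raise ConcordanceError(
            f"platform R2 never dropped below {r2_target} before percentiles "
            f"reached ({p_low:g}, {p_high:g}); trace attached",
            pd.DataFrame(rows),
        )


def find_nonconcordant(
    t_log2,
    r_log2,
    t_epm,
    r_epm,
    start=(10.0, 90.0),
    step: float = 1.0,
    r2_target: float = 0.10,
    gate_threshold: float = 5.0,
    scope: str = "all_genes",
    n_perm: int = 999,
    seed: int | None = None,
) -> ConcordanceResults:
    """Functional shorthand for ``ConcordanceModel(...).fit(...)``."""
    model = ConcordanceModel(t_log2, r_log2, t_epm, r_epm, gate_threshold, scope)
    return model.fit(start=start, step=step, r2_target=r2_target, n_perm=n_perm, seed=seed)


def fold_difference_summary(
    t_epm: ExpressionMatrix,
    r_epm: ExpressionMatrix,
    genes: pd.Index | None = None,
) -> dict:
    """Mean fold difference 2^|Δ| between platforms with a 95% t-interval.

    Each (gene, cell line) observation contributes 2^|Δ(g,c)|; the direction
    (which platform trends higher) is reported separately as the sign of the
    mean Δ.
    """
    _check_pair(t_epm, r_epm, "epm")
    t = np.log2(t_epm.data + 1.0)
    r = np.log2(r_epm.data + 1.0)
    delta = pd.DataFrame(t.to_numpy() - r.to_numpy(), index=t_epm.gene_ids)
    if genes is not None:
        delta = delta.loc[genes]
    vals = np.exp2(np.abs(delta.to_numpy()).ravel())
    mean = float(vals.mean())
    n = vals.size
    half = stats.t.ppf(0.975, n - 1) * vals.std(ddof=1) / np.sqrt(n) if n > 1 else 0.0
    sign = float(np.sign(delta.to_numpy().mean()))
    return {
        "mean_fold": mean,
        "ci_low": mean - half,
        "ci_high": mean + half,
        "n": int(n),
        "direction": "targeted_higher" if sign > 0 else (
            "reference_higher" if sign < 0 else "none"
        ),
    }


def threshold_counts(
    dp: DiffProfile,
    thresholds,
    gene_lists: dict[str, set] | None = None,
) -> pd.DataFrame:
    """Genes with mean |Δ| above each threshold, optionally tallied against
    user-supplied gene lists (symbol/id overlap counts)."""
    rows = []
    for th in thresholds:
        hits = dp.gene_mean_abs.index[dp.gene_mean_abs > th]
        row = {"threshold": th, "n_genes": len(hits)}
        if gene_lists:
            for name, members in gene_lists.items():
                row[f"n_in_{name}"] = len(set(hits) & set(members))
        rows.append(row)
    return pd.DataFrame(rows)
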