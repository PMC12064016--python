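"""Variance attribution on distance matrices and PC scores.

Implements, from their matrix-algebra definitions:

* :class:`Permanova` — permutational multivariate ANOVA with sequential
  (Type-I) sums of squares on a Euclidean (or any symmetric) distance matrix,
  pseudo-F statistics and permutation p-values;
* :class:`ComponentAnova` — the same sequential decomposition applied to a
  single principal-component score vector, with parametric F p-values;
* :class:`DispersionTest` — multivariate homogeneity of group dispersions
  (distance of each sample to its group center in PCoA space, one-way F).

All three follow the Model -> ``fit()`` -> Results pattern; results carry a
``table`` DataFrame (term, df, SS, R², statistic, p) and a ``summary()``.

The sequential decomposition uses nested hat matrices over dummy-coded
designs with intercept: for Gower-centered G and projectors
H_0 ⊂ H_1 ⊂ … ⊂ H_m, term k's sum of squares is tr(H_k G) − tr(H_{k−1} G);
R²_k = SS_k / tr(G); pseudo-F_k = (SS_k/df_k)/(SS_res/df_res).  Permutations
act on sample labels (rows/columns of G jointly), free across all terms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ordination import check_distance_matrix, gower_center


def _dummy(levels: pd.Series) -> np.ndarray:
    """Full dummy coding (one column per level) without intercept."""
    cats = pd.Categorical(levels)
    return np.eye(len(cats.categories))[cats.codes]


def _hat(X: np.ndarray) -> np.ndarray:
    """Orthogonal projector onto the column space of X (rank-safe via SVD)."""
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    U = U[:, s > 1e-10 * max(1.0, s.max())]
    return U @ U.T


def _nested_projectors(
    factors: pd.DataFrame, terms: list[str]
) -> tuple[list[np.ndarray], list[int]]:
    """Hat matrices for the nested designs [1], [1,A], [1,A,B], …"""
    n = len(factors)
    X = np.ones((n, 1))
    hats = [np.full((n, n), 1.0 / n)]
    dfs = []
    rank_prev = 1
    for t in terms:
        lv = factors[t]
        if lv.nunique() < 2:
            raise ValueError(f"term {t!r} has fewer than 2 levels")
        X = np.hstack([X, _dummy(lv)])
        H = _hat(X)
        rank = int(round(np.trace(H)))
        dfs.append(rank - rank_prev)
        rank_prev = rank
        hats.append(H)
    return hats, dfs


def _sequential_ss(G: np.ndarray, hats: list[np.ndarray]) -> tuple[np.ndarray, float]:
    """Per-term SS from nested projectors; returns (SS per term, SS_total)."""
    traces = [float(np.sum(H * G)) for H in hats]  # tr(H G), H symmetric
    ss = np.diff(traces)
    return ss, float(np.trace(G))


@dataclass
class VarianceAttribution:
    """Per-factor decomposition of (multivariate) variance.

    ``table`` rows are the model terms in order, then Residual and Total;
    columns: df, SS, R2, F, p, n_perm (PERMANOVA) or NaN (parametric).
    """

    table: pd.DataFrame
    method: str
    n_permutations: int | None = None
    seed: int | None = None

    def r2(self, term: str) -> float:
        return float(self.table.loc[term, "R2"])

    def p(self, term: str) -> float:
        return float(self.table.loc[term, "p"])

    def summary(self) -> str:
        head = f"{self.method} variance attribution"
        if self.n_permutations:
            head += f" ({self.n_permutations} permutations, seed={self.seed})"
        with pd.option_context("display.float_format", "{:0.4g}".format):
            return head + "\n" + self.table.to_string()


class Permanova:
    """Permutational multivariate ANOVA on a distance matrix.

    Parameters
    ----------
    distance :
        Square symmetric distance matrix (DataFrame or array), samples in
        rows/columns.
    factors :
        DataFrame of sample-level factors aligned with ``distance`` rows.
    terms :
        Ordered model terms (column names of ``factors``); order matters —
        sums of squares are sequential.
    """

    def __init__(self, distance, factors: pd.DataFrame, terms: list[str] | None = None):
        self.D = check_distance_matrix(distance)
        self.index = distance.index if hasattr(distance, "index") else None
        factors = pd.DataFrame(factors)
        if self.index is not None and not factors.index.equals(pd.Index(self.index)):
            factors = factors.reindex(self.index)
            if factors.isna().any().any():
                raise ValueError("factors do not cover all distance-matrix samples")
        if len(factors) != self.D.shape[0]:
            raise ValueError("factors length does not match distance matrix")
        self.factors = factors
        self.terms = list(terms) if terms is not None else list(factors.columns)

    def fit(self, n_perm: int = 999, seed: int | None = None) -> VarianceAttribution:
        """Decompose and, when ``n_perm > 0``, attach permutation p-values.

        R² values are permutation-free; only p depends on the seed.  The
        permutation p-value is (1 + #{F* >= F}) / (n_perm + 1) under free
        whole-row label permutation.
        """
        G = gower_center(self.D)
        hats, dfs = _nested_projectors(self.factors, self.terms)
        ss, ss_total = _sequential_ss(G, hats)
        ss = np.where(np.abs(ss) < 1e-12 * max(ss_total, 1.0), np.abs(ss), ss)
        n = G.shape[0]
        df_res = n - 1 - int(sum(dfs))
        ss_res = ss_total - float(ss.sum())
        ms_res = ss_res / df_res if df_res > 0 else np.nan
        with np.errstate(invalid="ignore", divide="ignore"):
            F = (ss / np.maximum(dfs, 1)) / ms_res if df_res > 0 else np.full(len(ss), np.nan)
            r2 = ss / ss_total if ss_total > 0 else np.zeros_like(ss)

        pvals = np.full(len(ss), np.nan)
        if n_perm > 0 and df_res > 0 and ss_total > 0:
            rng = np.random.default_rng(seed)
            exceed = np.zeros(len(ss))
            for _ in range(n_perm):
                perm = rng.permutation(n)
                Gp = G[np.ix_(perm, perm)]
                ssp, _ = _sequential_ss(Gp, hats)
                ssp_res = ss_total - float(ssp.sum())
                Fp = (ssp / np.maximum(dfs, 1)) / (ssp_res / df_res)
                exceed += Fp >= F - 1e-12
            pvals = (1.0 + exceed) / (n_perm + 1.0)

        rows = []
        for i, t in enumerate(self.terms):
            rows.append((t, dfs[i], ss[i], r2[i], F[i], pvals[i]))
        r2_res = ss_res / ss_total if ss_total > 0 else 0.0
        rows.append(("Residual", df_res, ss_res, r2_res, np.nan, np.nan))
        rows.append(("Total", n - 1, ss_total, 1.0 if ss_total > 0 else 0.0, np.nan, np.nan))
        table = pd.DataFrame(
            rows, columns=["term", "df", "SS", "R2", "F", "p"]
        ).set_index("term")
        return VarianceAttribution(table, "PERMANOVA", n_perm if n_perm > 0 else None, seed)


def permanova(
    distance, factors, terms=None, n_perm: int = 999, seed: int | None = None
) -> VarianceAttribution:
    """Functional shorthand for ``Permanova(...).fit(...)``."""
    return Permanova(distance, factors, terms).fit(n_perm=n_perm, seed=seed)


class ComponentAnova:
    """Sequential (Type-I) ANOVA of one PC score vector on ordered factors."""

    def __init__(self, scores: pd.Series, factors: pd.DataFrame, terms=None):
        self.y = np.asarray(scores, dtype=float)
        factors = pd.DataFrame(factors)
        if hasattr(scores, "index") and not factors.index.equals(scores.index):
            factors = factors.reindex(scores.index)
            if factors.isna().any().any():
                raise ValueError("factors do not cover all samples in the score vector")
        if len(factors) != len(self.y):
            raise ValueError("factors length does not match scores")
        self.factors = factors
        self.terms = list(terms) if terms is not None else list(factors.columns)

    def fit(self) -> VarianceAttribution:
        y = self.y
        n = len(y)
        hats, dfs = _nested_projectors(self.factors, self.terms)
        G = np.outer(y - y.mean(), y - y.mean())
        ss, ss_total = _sequential_ss(G, hats)
        ss = np.maximum(ss, 0.0)  # guard tiny negative round-off
        df_res = n - 1 - int(sum(dfs))
        ss_res = max(ss_total - float(ss.sum()), 0.0)
        rows = []
        for i, t in enumerate(self.terms):
            r2 = ss[i] / ss_total if ss_total > 0 else 0.0
            if df_res > 0 and ss_res > 0:
                F = (ss[i] / dfs[i]) / (ss_res / df_res)
                p = float(stats.f.sf(F, dfs[i], df_res))
            elif df_res > 0 and ss_res == 0:
                F = np.inf if ss[i] > 0 else 0.0
                p = 0.0 if ss[i] > 0 else 1.0
            else:  # saturated: R² reported, F/p undefined
                F, p = np.nan, np.nan
            rows.append((t, dfs[i], ss[i], r2, F, p))
        r2_res = ss_res / ss_total if ss_total > 0 else 0.0
        rows.append(("Residual", df_res, ss_res, r2_res, np.nan, np.nan))
        rows.append(("Total", n - 1, ss_total, 1.0 if ss_total > 0 else 0.0, np.nan, np.nan))
        table = pd.DataFrame(
            rows, columns=["term", "df", "SS", "R2", "F", "p"]
        ).set_index("term")
        return VarianceAttribution(table, "ANOVA")


def anova_on_component(scores, factors, terms=None) -> VarianceAttribution:
    """Functional shorthand for ``ComponentAnova(...).fit()``."""
    return ComponentAnova(scores, factors, terms).fit()


@dataclass
class DispersionResult:
    """Distances to group centers and the homogeneity-of-dispersion test."""

    distances: pd.Series            # per-sample distance to its group center
    group_means: pd.Series
    F: float
    p: float
    center: str
    singleton_groups: list[str]
    p_permutation: float | None = None

    def summary(self) -> str:
        lines = [
            f"Dispersion test (center={self.center}): F={self.F:0.4g}, p={self.p:0.4g}"
        ]
        if self.p_permutation is not None:
            lines.append(f"  permutation p={self.p_permutation:0.4g}")
        lines.append("  group mean distances:")
        for g, v in self.group_means.items():
            lines.append(f"    {g}: {v:0.4g}")
        if self.singleton_groups:
            lines.append(f"  singleton groups (dispersion undefined): {self.singleton_groups}")
        return "\n".join(lines)


class DispersionTest:
    """Multivariate homogeneity of group dispersions on a distance matrix.

    Samples are embedded by PCoA keeping real and imaginary axes separately;
    the distance of each sample to its group center is
    sqrt(max(d²_real − d²_imag, 0)), and a one-way parametric F compares the
    per-group mean distances.  ``center`` is the group centroid by default; a
    spatial-median variant (Weiszfeld iteration on the real axes) is exposed
    because reference implementations differ on this default.
    """

    def __init__(self, distance, group: pd.Series, center: str = "centroid"):
        if center not in ("centroid", "spatial_median"):
            raise ValueError(f"unknown center {center!r}")
        self.D = check_distance_matrix(distance)
        idx = distance.index if hasattr(distance, "index") else range(self.D.shape[0])
        self.group = pd.Series(np.asarray(group), index=idx)
        if self.group.nunique() < 2:
            raise ValueError("dispersion test needs at least 2 groups")
        self.center = center

    @staticmethod
    def _spatial_median(X: np.ndarray, n_iter: int = 200, tol: float = 1e-10) -> np.ndarray:
        m = X.mean(axis=0)
        for _ in range(n_iter):
            d = np.linalg.norm(X - m, axis=1)
            if (d < tol).any():
                return X[d < tol][0]
            w = 1.0 / d
            new = (X * w[:, None]).sum(axis=0) / w.sum()
            if np.linalg.norm(new - m) < tol:
                return new
            m = new
        return m

    def fit(self, n_perm: int = 0, seed: int | None = None) -> DispersionResult:
        G = gower_center(self.D)
        vals, vecs = np.linalg.eigh((G + G.T) / 2)
        order = np.argsort(vals)[::-1]
        vals, vecs = vals[order], vecs[:, order]
        tol = 1e-8 * max(abs(vals).max(), 1.0)
        pos, neg = vals > tol, vals < -tol
        Xp = vecs[:, pos] * np.sqrt(vals[pos])
        Xn = vecs[:, neg] * np.sqrt(-vals[neg])
        idx = self.group.index

        dist = pd.Series(0.0, index=idx)
        singletons = []
        for g, members in self.group.groupby(self.group).groups.items():
            rows = idx.get_indexer(members)
            if len(rows) == 1:
                singletons.append(str(g))
            if self.center == "centroid" or len(rows) == 1:
                cp = Xp[rows].mean(axis=0)
            else:
                cp = self._spatial_median(Xp[rows])
            cn = Xn[rows].mean(axis=0) if Xn.shape[1] else np.zeros(0)
            d2 = ((Xp[rows] - cp) ** 2).sum(axis=1)
            if Xn.shape[1]:
                d2 = d2 - ((Xn[rows] - cn) ** 2).sum(axis=1)
            dist.iloc[rows] = np.sqrt(np.clip(d2, 0.0, None))

        F, p = self._anova_f(dist, self.group)
        gm = dist.groupby(self.group).mean()
        p_perm = None
        if n_perm > 0 and np.isfinite(F):
            rng = np.random.default_rng(seed)
            labels = self.group.to_numpy()
            exceed = 0
            for _ in range(n_perm):
                Fp, _ = self._anova_f(dist, pd.Series(rng.permutation(labels), index=idx))
                exceed += Fp >= F - 1e-12
            p_perm = (1.0 + exceed) / (n_perm + 1.0)
        return DispersionResult(dist, gm, F, p, self.center, singletons, p_perm)

    @staticmethod
    def _anova_f(dist: pd.Series, group: pd.Series) -> tuple[float, float]:
        groups = [v.to_numpy() for _, v in dist.groupby(group)]
        k, n = len(groups), len(dist)
        grand = dist.mean()
        ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
        if ssw <= 0 or n - k <= 0:
            return (np.nan, np.nan)  # degenerate: all distances coincide
        F = (ssb / (k - 1)) / (ssw / (n - k))
        return float(F), float(stats.f.sf(F, k - 1, n - k))


def dispersion_test(
    distance, group, center: str = "centroid", n_perm: int = 0, seed=None
) -> DispersionResult:
    """Functional shorthand for ``DispersionTest(...).fit(...)``."""
    return DispersionTest(distance, group, center).fit(n_perm=n_perm, seed=seed)
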