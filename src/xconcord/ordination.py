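"""Ordination primitives: PCA from the SVD, Euclidean distances, classical
PCoA (metric MDS), and high-loading gene extraction.

Conventions match the usual ``prcomp`` behaviour: samples are observations,
genes are variables, data are centered (optionally scaled) before the
singular-value decomposition, and eigenvalues are variances (s^2 / (n-1)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .matrix import ExpressionMatrix


@dataclass
class OrdinationResult:
    """Scores, loadings and eigen-spectrum of a PCA or PCoA."""

    scores: pd.DataFrame                  # samples x components
    loadings: pd.DataFrame | None         # genes x components (PCA only)
    eigenvalues: np.ndarray               # variance per component, nonincreasing
    variance_fraction: np.ndarray
    center: pd.Series | None = None

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def _as_samples_by_genes(m) -> pd.DataFrame:
    if isinstance(m, ExpressionMatrix):
        return m.data.T
    return pd.DataFrame(m)


def pca(m, center: bool = True, scale: bool = False) -> OrdinationResult:
    """Principal component analysis of an expression matrix.

    ``m`` is an :class:`ExpressionMatrix` (genes x samples) or a DataFrame of
    samples x features.  Data are centered by default and not scaled, since
    both platforms are already on equivalent units.  Components retained:
    min(n_samples - 1, n_features) when centering (the centered matrix has at
    most rank n-1).
    """
    X = _as_samples_by_genes(m)
    n, p = X.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 samples")
    vals = X.to_numpy(dtype=float)
    mean = vals.mean(axis=0) if center else np.zeros(p)
    Xc = vals - mean
    if scale:
        sd = vals.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    k = min(n - 1, p) if center else min(n, p)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    U, s, Vt = U[:, :k], s[:k], Vt[:k]
    eig = s**2 / (n - 1)
    total = eig.sum()
    frac = eig / total if total > 0 else np.zeros_like(eig)
    comp = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame(U * s, index=X.index, columns=comp)
    loadings = pd.DataFrame(Vt.T, index=X.columns, columns=comp)
    return OrdinationResult(
        scores, loadings, eig, frac, pd.Series(mean, index=X.columns)
    )


def euclidean_distance(scores: pd.DataFrame) -> pd.DataFrame:
    """Square symmetric Euclidean distance matrix over rows (samples)."""
    D = squareform(pdist(np.asarray(scores, dtype=float), metric="euclidean"))
    idx = scores.index if hasattr(scores, "index") else None
    return pd.DataFrame(D, index=idx, columns=idx)


def check_distance_matrix(D: pd.DataFrame, tol: float = 1e-8) -> np.ndarray:
    A = np.asarray(D, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(A, A.T, atol=tol):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(A), 0.0, atol=tol):
        raise ValueError("distance matrix must have zero diagonal")
    if (A < -tol).any():
        raise ValueError("distance matrix must be non-negative")
    return A


def gower_center(D) -> np.ndarray:
    """Gower-centered inner-product matrix G = C (-1/2 D∘D) C."""
    A = check_distance_matrix(D)
    n = A.shape[0]
    B = -0.5 * A**2
    C = np.eye(n) - np.ones((n, n)) / n
    return C @ B @ C


def pcoa(D, eig_tol: float = 1e-9) -> OrdinationResult:
    """Classical principal coordinate analysis of a distance matrix.

    Eigendecomposition of the double-centered -1/2 D^2 matrix; coordinates
    are returned for axes with positive eigenvalues.  For a Euclidean D the
    coordinates reproduce PCA scores of the underlying data up to sign.
    """
    G = gower_center(D)
    vals, vecs = np.linalg.eigh((G + G.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > eig_tol * max(vals.max(), 1.0)
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    idx = D.index if hasattr(D, "index") else None
    comp = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    pos_sum = vals[pos].sum()
    frac = vals[pos] / pos_sum if pos_sum > 0 else np.zeros(pos.sum())
    return OrdinationResult(
        pd.DataFrame(coords, index=idx, columns=comp), None, vals, frac
    )


def high_loading_genes(
    loadings: pd.DataFrame, component: str | int = "PC1", threshold: float = 0.02
) -> pd.Series:
    """Genes whose |loading| on a component exceeds ``threshold``.

    Returns the signed loadings sorted by absolute value, descending —
    the genes at the tails of the rotation-score distribution that drive
    the component.
    """
    col = f"PC{component}" if isinstance(component, int) else component
    if col not in loadings.columns:
        raise KeyError(f"component {col!r} not in loadings")
    v = loadings[col]
    hits = v[v.abs() > threshold]
    return hits.reindex(hits.abs().sort_values(ascending=False).index)
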