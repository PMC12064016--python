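"""Synthetic dual-platform expression data with planted ground truth.

The generator emulates the structure of a targeted-sequencing vs
whole-transcriptome comparison: both platforms measure the same gene
universe; every cell line has its own expression signature shared across
platforms; a planted subset of genes carries a platform-specific log2 bias
(constant across cell lines, half up / half down); replicates add log-scale
Gaussian noise; the targeted platform emits several probe rows per gene and
integer counts at a configurable library size, while the reference platform
emits expression-per-million directly (one sample per cell line, as public
whole-transcriptome compendia distribute replicate-averaged values only).

Expected log2 expression of gene g in cell line c:

    targeted :  baseline(g) + cellEffect(g, c) + bias(g) * [g planted]
    reference:  baseline(g) + cellEffect(g, c)

Log2 values are mapped to relative abundances via w = 2^x - 1 (so that a
library normalized to its own total reproduces log2(EPM+1) = x up to a
per-sample scale shift) and rounded to counts; a fraction of genes is
universally unexpressed (all-zero on both platforms).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, ProbeCountMatrix, SampleAnnotation


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the dual-platform simulation (log2 units throughout)."""

    n_genes: int = 2000
    n_cell_lines: int = 12
    n_replicates_per_platform: int = 3
    frac_platform_biased: float = 0.2
    bias_log2_range: tuple[float, float] = (2.0, 8.0)
    frac_unexpressed: float = 0.05
    baseline_log2_mean_range: tuple[float, float] = (0.0, 12.0)
    cell_line_effect_sd: float = 1.0
    replicate_noise_sd: float = 0.25
    library_size_range: tuple[float, float] = (4.5e6, 6.0e6)
    probes_per_gene_max: int = 3
    frac_marker_genes: float = 0.1
    marker_effect_sd: float = 3.0
    poisson_counts: bool = False
    seed: int = 0

    def validate(self) -> None:
        def _finite(name, *vals):
            for v in vals:
                if not np.isfinite(v):
                    raise ValueError(f"non-finite value for {name}")

        for name in (
            "frac_platform_biased",
            "frac_unexpressed",
            "frac_marker_genes",
        ):
            v = getattr(self, name)
            _finite(name, v)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "bias_log2_range",
            "baseline_log2_mean_range",
            "library_size_range",
        ):
            lo, hi = getattr(self, name)
            _finite(name, lo, hi)
            if lo > hi:
                raise ValueError(f"{name} must have low <= high, got {(lo, hi)}")
        for name in ("cell_line_effect_sd", "replicate_noise_sd", "marker_effect_sd"):
            v = getattr(self, name)
            _finite(name, v)
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.n_genes < 10:
            raise ValueError(f"n_genes must be >= 10, got {self.n_genes}")
        for name in ("n_cell_lines", "n_replicates_per_platform", "probes_per_gene_max"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.library_size_range[0] <= 0:
            raise ValueError("library_size_range must be positive")


@dataclass
class SyntheticTruth:
    """Planted ground truth emitted alongside every simulated data set."""

    bias_log2: pd.Series           # signed planted bias, biased genes only
    unexpressed_genes: set[str]
    baseline_log2: pd.Series       # expressed genes
    cell_effects: pd.DataFrame     # genes x cell lines (expressed genes)
    seed: int

    @property
    def biased_genes(self) -> set[str]:
        return set(self.bias_log2.index)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "bias_log2": self.bias_log2.to_dict(),
            "unexpressed_genes": sorted(self.unexpressed_genes),
            "baseline_log2": self.baseline_log2.to_dict(),
            "cell_lines": list(self.cell_effects.columns),
        }


def _gene_ids(n: int) -> pd.Index:
    return pd.Index([f"ENSG{i:011d}" for i in range(1, n + 1)], name="ensembl_id")


def _make_truth(config: SimConfig, rng: np.random.Generator) -> SyntheticTruth:
    genes = _gene_ids(config.n_genes)
    cells = [f"CL{i + 1:02d}" for i in range(config.n_cell_lines)]

    n_unexp = int(round(config.frac_unexpressed * config.n_genes))
    unexpressed = set(rng.choice(genes, size=n_unexp, replace=False)) if n_unexp else set()
    expressed = genes[~genes.isin(unexpressed)]
    n_expr = len(expressed)

    lo, hi = config.baseline_log2_mean_range
    baseline = pd.Series(rng.uniform(lo, hi, size=n_expr), index=expressed)

    n_biased = int(round(config.frac_platform_biased * n_expr))
    biased = rng.choice(expressed, size=n_biased, replace=False) if n_biased else []
    blo, bhi = config.bias_log2_range
    mags = rng.uniform(blo, bhi, size=n_biased)
    signs = np.ones(n_biased)
    signs[n_biased // 2 :] = -1.0      # half up / half down
    signs = rng.permutation(signs)
    bias = pd.Series(mags * signs, index=pd.Index(biased, name="ensembl_id"))
    # Mass balance: redraw biased-gene baselines so that both the biased and
    # unbiased log2 values lie inside the global dynamic range (up-biased
    # genes from the low end, down-biased from the high end).  The linear
    # mass added by up-biased genes then cancels, in expectation, the mass
    # removed by down-biased ones, keeping both platforms' library totals
    # equal — per-million normalization would otherwise turn a one-sided
    # mass change into a global log2 shift of every unbiased gene.
    if n_biased:
        if bhi > hi - lo:
            raise ValueError(
                "bias_log2_range exceeds the baseline dynamic range; "
                "mass-balanced planting impossible"
            )
        b_lo = np.where(signs < 0, lo + mags, lo)
        b_hi = np.where(signs < 0, hi, hi - mags)
        baseline.loc[bias.index] = rng.uniform(b_lo, b_hi)

    # marker genes get large cell-line effects so ordination separates lines
    n_marker = int(round(config.frac_marker_genes * n_expr))
    marker = rng.choice(expressed, size=n_marker, replace=False) if n_marker else []
    sds = pd.Series(config.cell_line_effect_sd, index=expressed)
    sds.loc[marker] = config.marker_effect_sd
    effects = pd.DataFrame(
        rng.normal(0.0, 1.0, size=(n_expr, config.n_cell_lines))
        * sds.to_numpy()[:, None],
        index=expressed,
        columns=cells,
    )
    return SyntheticTruth(bias, unexpressed, baseline, effects, config.seed)


def _abundance(log2_expr: np.ndarray) -> np.ndarray:
    """Map log2 expression to relative abundance: w = 2^x - 1, clipped at 0."""
    return np.clip(np.exp2(log2_expr) - 1.0, 0.0, None)


def _to_counts(
    w: np.ndarray, library_size: float, rng: np.random.Generator, poisson: bool
) -> np.ndarray:
    total = w.sum()
    if total <= 0:
        return np.zeros_like(w, dtype=np.int64)
    lam = w / total * library_size
    if poisson:
        return rng.poisson(lam).astype(np.int64)
    return np.rint(lam).astype(np.int64)


def _expected_log2(
    truth: SyntheticTruth, genes: pd.Index, cell: str, targeted: bool
) -> pd.Series:
    x = pd.Series(0.0, index=genes)
    expr = truth.baseline_log2.index
    x.loc[expr] = truth.baseline_log2 + truth.cell_effects[cell]
    if targeted and len(truth.bias_log2):
        x.loc[truth.bias_log2.index] += truth.bias_log2
    x.loc[sorted(truth.unexpressed_genes)] = -np.inf  # maps to w = 0
    return x


def _noisy(x: pd.Series, sd: float, rng: np.random.Generator) -> np.ndarray:
    noise = rng.normal(0.0, sd, size=len(x)) if sd > 0 else 0.0
    return np.where(np.isneginf(x.to_numpy()), -np.inf, x.to_numpy() + noise)


def _emit_probes(
    gene_counts: pd.DataFrame, probes_per_gene_max: int, rng: np.random.Generator
) -> ProbeCountMatrix:
    """Expand gene-level counts into 1..max probe rows per gene.

    The first probe of each gene carries the gene-level count, so the
    per-sample maximum over a gene's probes recovers it exactly; the
    remaining probes draw uniformly in [0, gene count].
    """
    genes = gene_counts.index
    k = rng.integers(1, probes_per_gene_max + 1, size=len(genes))
    rows, probe_ids, probe_genes = [], [], []
    counts = gene_counts.to_numpy()
    for j in range(1, probes_per_gene_max + 1):
        sel = k >= j
        if not sel.any():
            continue
        sub = counts[sel]
        vals = sub if j == 1 else rng.integers(0, sub + 1)
        rows.append(vals)
        probe_ids.extend(f"{g}_p{j}" for g in genes[sel])
        probe_genes.extend(genes[sel])
    mat = pd.DataFrame(
        np.vstack(rows), index=pd.Index(probe_ids, name="probe_id"),
        columns=gene_counts.columns,
    ).sort_index()
    manifest = pd.DataFrame(
        {
            "gene_symbol": [f"SYM{g[-5:]}" for g in probe_genes],
            "ensembl_id": probe_genes,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    ).sort_index()
    return ProbeCountMatrix(mat, manifest)


def generate_dual_platform(
    config: SimConfig,
) -> tuple[ProbeCountMatrix, ExpressionMatrix, SampleAnnotation, SyntheticTruth]:
    """Simulate matched targeted-platform counts and reference-platform EPM.

    Returns probe-level counts for the targeted platform (with replicates),
    an EPM matrix for the reference platform (one sample per cell line), the
    sample annotation for both, and the planted truth.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth = _make_truth(config, rng)
    genes = _gene_ids(config.n_genes)
    cells = list(truth.cell_effects.columns)

    ann_rows = []
    t_cols: dict[str, np.ndarray] = {}
    for cell in cells:
        mu = _expected_log2(truth, genes, cell, targeted=True)
        for rep in range(1, config.n_replicates_per_platform + 1):
            w = _abundance(_noisy(mu, config.replicate_noise_sd, rng))
            lib = rng.uniform(*config.library_size_range)
            name = f"T_{cell}_r{rep}"
            t_cols[name] = _to_counts(w, lib, rng, config.poisson_counts)
            ann_rows.append((name, cell, "TARGETED", "none", rep))
    gene_counts = pd.DataFrame(t_cols, index=genes)
    probes = _emit_probes(gene_counts, config.probes_per_gene_max, rng)

    r_cols: dict[str, np.ndarray] = {}
    for cell in cells:
        mu = _expected_log2(truth, genes, cell, targeted=False)
        w = _abundance(_noisy(mu, config.replicate_noise_sd, rng))
        total = w.sum()
        name = f"R_{cell}"
        r_cols[name] = w / total * 1e6 if total > 0 else np.zeros_like(w)
        ann_rows.append((name, cell, "REFERENCE", "none", 1))
    reference = ExpressionMatrix(pd.DataFrame(r_cols, index=genes), "epm")

    ann = SampleAnnotation(
        pd.DataFrame(
            ann_rows, columns=["sample_id", "cell_line", "platform", "phase", "replicate"]
        ).set_index("sample_id")
    )
    return probes, reference, ann, truth


def generate_replicate_phases(
    config: SimConfig,
    n_phases: int = 2,
    depth_factors: Sequence[float] | None = None,
) -> tuple[list[ProbeCountMatrix], SampleAnnotation, SyntheticTruth]:
    """Simulate the targeted platform across several acquisition phases.

    Phases share all generative parameters; they differ only in total library
    size (scaled by the phase's depth factor) and fresh replicate noise.
    """
    config.validate()
    if n_phases < 2:
        raise ValueError(f"n_phases must be >= 2, got {n_phases}")
    if depth_factors is None:
        depth_factors = [1.0] * n_phases
    depth_factors = list(depth_factors)
    if len(depth_factors) != n_phases:
        raise ValueError(
            f"expected {n_phases} depth factors, got {len(depth_factors)}"
        )
    if any((not np.isfinite(f)) or f <= 0 for f in depth_factors):
        raise ValueError(f"depth factors must be positive, got {depth_factors}")

    rng = np.random.default_rng(config.seed)
    truth = _make_truth(config, rng)
    genes = _gene_ids(config.n_genes)
    cells = list(truth.cell_effects.columns)

    ann_rows = []
    phase_matrices = []
    for p, factor in enumerate(depth_factors, start=1):
        cols: dict[str, np.ndarray] = {}
        for cell in cells:
            mu = _expected_log2(truth, genes, cell, targeted=True)
            for rep in range(1, config.n_replicates_per_platform + 1):
                w = _abundance(_noisy(mu, config.replicate_noise_sd, rng))
                lib = rng.uniform(*config.library_size_range) * factor
                name = f"T_{cell}_P{p}_r{rep}"
                cols[name] = _to_counts(w, lib, rng, config.poisson_counts)
                ann_rows.append((name, cell, "TARGETED", str(p), rep))
        gene_counts = pd.DataFrame(cols, index=genes)
        phase_matrices.append(
            _emit_probes(gene_counts, config.probes_per_gene_max, rng)
        )
    ann = SampleAnnotation(
        pd.DataFrame(
            ann_rows, columns=["sample_id", "cell_line", "platform", "phase", "replicate"]
        ).set_index("sample_id")
    )
    return phase_matrices, ann, truth
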