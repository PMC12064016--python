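"""Probe collapse, expression-per-million normalization, log transform,
replicate averaging and cross-platform harmonization.

The normalization chain is: probe counts -> gene counts (per-sample maximum
over a gene's probes) -> EPM (each sample rescaled to a total of 1e6) ->
log2(EPM+1).  Two platforms are harmonized by intersecting on Ensembl id and
rescaling the surviving genes back to 1e6 per sample, so that counts-per-
million and transcripts-per-million columns stay directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, ProbeCountMatrix, SampleAnnotation

EPM_TOTAL = 1_000_000.0
EPM_TOL = 0.01


def collapse_probes(pm: ProbeCountMatrix) -> ExpressionMatrix:
    """Collapse a probe-level count matrix to one row per Ensembl gene.

    For a gene measured by several probes the per-sample maximum count is
    taken, each sample independently.  Genes whose probes are all zero are
    kept with value 0.
    """
    if pm.counts.empty:
        raise ValueError("probe count matrix is empty")
    genes = pm.manifest.loc[pm.counts.index, "ensembl_id"]
    collapsed = pm.counts.groupby(genes, sort=True).max()
    collapsed.index.name = "ensembl_id"
    symbols = (
        pm.manifest.loc[pm.counts.index]
        .groupby("ensembl_id", sort=True)["gene_symbol"]
        .first()
    )
    return ExpressionMatrix(collapsed, "counts", symbols)


def epm_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Rescale every sample column to a total of one million (EPM).

    Accepts raw counts or an already-EPM matrix whose columns no longer sum
    to 1e6 (e.g. after dropping genes); idempotent on valid EPM input.
    """
    if m.unit not in ("counts", "epm"):
        raise ValueError(f"cannot EPM-normalize unit {m.unit!r}")
    totals = m.data.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"samples with non-positive total: {zero.index[:5].tolist()}")
    return m.with_data(m.data * (EPM_TOTAL / totals), "epm")


def log2p1(m: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise log2(EPM + 1); zero maps to zero so sparsity is preserved."""
    if m.unit != "epm":
        raise ValueError(f"log2p1 expects EPM input, got {m.unit!r}")
    if (m.data.to_numpy() < 0).any():
        raise ValueError("negative expression values")
    return m.with_data(np.log2(m.data + 1.0), "log2epm1")


def average_replicates(
    m: ExpressionMatrix,
    ann: SampleAnnotation,
    by: tuple[str, ...] = ("cell_line",),
) -> tuple[ExpressionMatrix, SampleAnnotation]:
    """Arithmetic per-gene mean of EPM over replicate groups.

    ``by`` names annotation columns defining the groups (default one group per
    cell line, pooling phases and replicates).  Each replicate carries equal
    weight regardless of phase.  Returns the averaged matrix (one sample per
    group, named by the joined group key) and a collapsed annotation.
    """
    if m.unit != "epm":
        raise ValueError(f"average_replicates expects EPM input, got {m.unit!r}")
    ann.require_samples(m.sample_ids)
    for key in by:
        if key not in ann.table.columns:
            raise ValueError(f"grouping key {key!r} absent from annotation")
    sub = ann.table.loc[m.sample_ids]
    groups = sub.groupby(list(by), sort=True, observed=True)
    cols, rows = {}, []
    for key, g in groups:
        key_t = key if isinstance(key, tuple) else (key,)
        name = "_".join(str(k) for k in key_t)
        cols[name] = m.data[g.index].mean(axis=1)
        rows.append(
            {
                "sample_id": name,
                "cell_line": g["cell_line"].iloc[0],
                "platform": g["platform"].iloc[0],
                "phase": key_t[by.index("phase")] if "phase" in by else "none",
                "replicate": 1,
            }
        )
    out = pd.DataFrame(cols, index=m.data.index)
    new_ann = SampleAnnotation(pd.DataFrame(rows).set_index("sample_id"))
    return m.with_data(out, "epm"), new_ann


def intersect_and_rescale(
    a: ExpressionMatrix, b: ExpressionMatrix
) -> tuple[ExpressionMatrix, ExpressionMatrix, dict]:
    """Reduce two EPM matrices to their shared Ensembl genes and renormalize.

    Returns both matrices on the identical, identically ordered gene set, each
    sample rescaled back to 1e6, plus a report dict with the gene bookkeeping.
    """
    if a.unit != "epm" or b.unit != "epm":
        raise ValueError("intersect_and_rescale expects two EPM matrices")
    shared = a.gene_ids.intersection(b.gene_ids).sort_values()
    if len(shared) == 0:
        raise ValueError("empty gene intersection between platforms")
    report = {
        "n_a": len(a.gene_ids),
        "n_b": len(b.gene_ids),
        "n_shared": len(shared),
        "n_a_only": len(a.gene_ids) - len(shared),
        "n_b_only": len(b.gene_ids) - len(shared),
    }
    a2 = epm_normalize(a.with_data(a.data.loc[shared], "epm"))
    b2 = epm_normalize(b.with_data(b.data.loc[shared], "epm"))
    return a2, b2, report
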