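"""End-to-end orchestration of the two study designs.

``run_tvt`` compares two (or more) acquisition phases of the targeted
platform: probe collapse -> EPM -> log2 -> replicate correlations within and
between phases -> PCA -> per-PC ANOVA (~cell_line + phase) -> PERMANOVA ->
dispersion tests -> PCoA.

``run_tvr`` compares the targeted platform against a reference
whole-transcriptome EPM table: collapse -> EPM -> replicate averaging ->
gene intersection/rescale -> log2 -> cross-platform correlations ->
PCA / ANOVA / PERMANOVA (~platform) -> difference profile -> stepwise
non-concordant-gene determination -> RLE correction -> repeated ordination
and correlation analysis -> optional gene-set enrichment.

Both return a :class:`RunReport` whose ``report`` dict is a pure function of
(inputs, config); TSV/JSON artifacts are written when ``out_dir`` is given.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as xio
from .concordance import (
    ConcordanceModel,
    average_median_diff,
    fold_difference_summary,
)
from .correlation import (
    matched_pair_values,
    pearson_matrix,
    replicate_pair_values,
    summarize_correlations,
)
from .enrichment import EnrichmentAnalysis, read_gmt
from .matrix import ExpressionMatrix, ProbeCountMatrix, SampleAnnotation
from .normalize import (
    average_replicates,
    collapse_probes,
    epm_normalize,
    intersect_and_rescale,
    log2p1,
)
from .ordination import euclidean_distance, pca, pcoa
from .permanova import ComponentAnova, DispersionTest, Permanova
from .rle import rle_normalize, rle_pipeline_rerun

__version__ = "0.1.0"


@dataclass
class RunConfig:
    """All stage parameters for the orchestrated runs."""

    gate_threshold: float = 5.0
    r2_target: float = 0.10
    percentile_start: tuple[float, float] = (10.0, 90.0)
    percentile_step: float = 1.0
    percentile_scope: str = "all_genes"
    n_perm: int = 999
    seed: int = 0
    dispersion_center: str = "centroid"
    enrichment_min_genes: int = 10
    enrichment_min_frac: float = 0.5
    fdr_threshold: float = 0.05
    gmt_path: str | None = None

    def echo(self) -> dict:
        d = self.__dict__.copy()
        d["percentile_start"] = list(self.percentile_start)
        return d


@dataclass
class RunReport:
    """Machine-readable record of one pipeline run."""

    design: str
    config: dict
    gene_counts: dict = field(default_factory=dict)
    tables: dict = field(default_factory=dict)
    results: dict = field(default_factory=dict)
    version: str = __version__

    def to_dict(self) -> dict:
        return {
            "design": self.design,
            "version": self.version,
            "config": self.config,
            "gene_counts": self.gene_counts,
            "tables": self.tables,
            "results": self.results,
        }

    def write(self, path: str | Path) -> None:
        xio.write_json(self.to_dict(), path)


def _att_dict(att) -> dict:
    return {
        term: {
            k: (None if (isinstance(v, float) and not np.isfinite(v)) else v)
            for k, v in row.items()
        }
        for term, row in att.table.to_dict(orient="index").items()
    }


def run_tvt(
    phase_probes: list[ProbeCountMatrix],
    annotation: SampleAnnotation,
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
) -> RunReport:
    """Phase-vs-phase replicate comparison on the targeted platform."""
    config = config or RunConfig()
    report = RunReport("tvt", config.echo())

    counts = [collapse_probes(pm) for pm in phase_probes]
    genes0 = counts[0].gene_ids
    for c in counts[1:]:
        if not c.gene_ids.equals(genes0):
            raise ValueError("phases must share the same gene universe")
    merged = counts[0].with_data(
        pd.concat([c.data for c in counts], axis=1), "counts"
    )
    annotation.require_samples(merged.sample_ids)
    report.gene_counts = {
        "n_probes": sum(len(pm.probe_ids) for pm in phase_probes),
        "n_genes": len(merged.gene_ids),
    }
    epm = epm_normalize(merged)
    logm = log2p1(epm)

    cells = annotation.factor("cell_line", logm.sample_ids)
    phases = annotation.factor("phase", logm.sample_ids).astype(str)

    # replicate correlations within each phase
    corr_summaries = []
    all_within = []
    for ph in sorted(phases.unique()):
        cols = logm.sample_ids[phases == ph]
        sub = logm.subset_samples(cols)
        vals = replicate_pair_values(pearson_matrix(sub), cells)
        all_within.extend(vals)
        corr_summaries.append(summarize_correlations(vals, f"within_phase_{ph}").as_row())
    corr_summaries.append(
        summarize_correlations(all_within, "within_phase_all").as_row()
    )

    # between phases on replicate-averaged data, matched cell lines
    phase_means = {}
    for ph in sorted(phases.unique()):
        cols = logm.sample_ids[phases == ph]
        sub_epm = epm.subset_samples(cols)
        avg, avg_ann = average_replicates(
            sub_epm, annotation.subset(cols), by=("cell_line",)
        )
        phase_means[ph] = log2p1(epm_normalize(avg))
    ph_ids = sorted(phase_means)
    between_vals = []
    for i, a in enumerate(ph_ids):
        for b in ph_ids[i + 1 :]:
            cross = pearson_matrix(phase_means[a], phase_means[b])
            between_vals.extend(np.diag(cross.to_numpy()))
    corr_summaries.append(
        summarize_correlations(between_vals, "between_phase").as_row()
    )

    ord_res = pca(logm)
    factors = pd.DataFrame({"cell_line": cells, "phase": phases})
    anova1 = ComponentAnova(
        ord_res.scores["PC1"], factors, ["cell_line", "phase"]
    ).fit()
    D = euclidean_distance(ord_res.scores)
    perm = Permanova(D, factors, ["cell_line", "phase"]).fit(
        n_perm=config.n_perm, seed=config.seed
    )
    disp_phase = DispersionTest(D, factors["phase"], config.dispersion_center).fit()
    disp_cell = DispersionTest(D, factors["cell_line"], config.dispersion_center).fit()
    coords = pcoa(D)

    report.tables = {
        "correlation_summaries": corr_summaries,
        "anova_pc1": _att_dict(anova1),
        "permanova": _att_dict(perm),
    }
    report.results = {
        "pc_variance_fraction": ord_res.variance_fraction[:5].tolist(),
        "dispersion_phase": {"F": disp_phase.F, "p": disp_phase.p},
        "dispersion_cell_line": {"F": disp_cell.F, "p": disp_cell.p},
        "permanova_r2": {t: perm.r2(t) for t in ("cell_line", "phase")},
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        xio.write_expression_table(logm, out / "log2_epm.tsv")
        ord_res.scores.to_csv(out / "pca_scores.tsv", sep="\t")
        D.to_csv(out / "distances.tsv", sep="\t")
        coords.scores.to_csv(out / "pcoa_coordinates.tsv", sep="\t")
        perm.table.to_csv(out / "permanova.tsv", sep="\t")
        anova1.table.to_csv(out / "anova_pc1.tsv", sep="\t")
        pd.DataFrame(corr_summaries).to_csv(
            out / "correlation_summaries.tsv", sep="\t", index=False
        )
        report.write(out / "run_report.json")
    return report


def run_tvr(
    probes: ProbeCountMatrix,
    reference_epm: ExpressionMatrix,
    annotation: SampleAnnotation,
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
) -> RunReport:
    """Platform-vs-platform comparison: targeted counts vs reference EPM."""
    config = config or RunConfig()
    report = RunReport("tvr", config.echo())

    t_counts = collapse_probes(probes)
    annotation.require_samples(t_counts.sample_ids)
    annotation.require_samples(reference_epm.sample_ids)
    t_epm_rep = epm_normalize(t_counts)
    t_ann = annotation.subset(t_counts.sample_ids)
    t_avg, t_avg_ann = average_replicates(t_epm_rep, t_ann, by=("cell_line",))
    r_epm_in = epm_normalize(reference_epm)
    r_ann = annotation.subset(reference_epm.sample_ids)
    # name reference columns by cell line so both platforms align by cell line
    r_cells = r_ann.factor("cell_line", r_epm_in.sample_ids)
    r_by_cell = r_epm_in.with_data(
        r_epm_in.data.set_axis(list(r_cells), axis=1), "epm"
    )
    order = sorted(set(t_avg.sample_ids) & set(r_by_cell.sample_ids))
    if not order:
        raise ValueError("no overlapping cell lines between platforms")
    t_avg = t_avg.subset_samples(order)
    r_by_cell = r_by_cell.subset_samples(order)

    t_epm, r_epm, isect = intersect_and_rescale(t_avg, r_by_cell)
    report.gene_counts = {
        "n_probes": len(probes.probe_ids),
        "n_targeted_genes": len(t_counts.gene_ids),
        "n_reference_genes": len(reference_epm.gene_ids),
        **isect,
    }
    t_log2, r_log2 = log2p1(t_epm), log2p1(r_epm)

    corr = pearson_matrix(t_log2, r_log2)
    cells = pd.Series(order, index=order)
    pairs = matched_pair_values(corr, cells, cells)
    corr_summaries = [
        summarize_correlations(pairs["matching"], "cross_platform_matching").as_row(),
        summarize_correlations(
            pairs["non_matching"], "cross_platform_non_matching"
        ).as_row(),
    ]

    X = pd.concat([t_log2.data.T, r_log2.data.T])
    X.index = [f"T_{c}" for c in order] + [f"R_{c}" for c in order]
    platform = pd.DataFrame(
        {"platform": ["TARGETED"] * len(order) + ["REFERENCE"] * len(order)},
        index=X.index,
    )
    ord_res = pca(X)
    anova1 = ComponentAnova(ord_res.scores["PC1"], platform, ["platform"]).fit()
    D = euclidean_distance(X)
    perm_log2 = Permanova(D, platform, ["platform"]).fit(
        n_perm=config.n_perm, seed=config.seed
    )
    disp_log2 = DispersionTest(D, platform["platform"], config.dispersion_center).fit()

    model = ConcordanceModel(
        t_log2, r_log2, t_epm, r_epm, config.gate_threshold, config.percentile_scope
    )
    conc = model.fit(
        start=config.percentile_start,
        step=config.percentile_step,
        r2_target=config.r2_target,
        n_perm=config.n_perm,
        seed=config.seed,
    )

    fold_all = fold_difference_summary(t_epm, r_epm)
    fold_conc = fold_difference_summary(
        t_epm, r_epm, conc.concordant_expressed_genes
    )
    corr_conc = pearson_matrix(
        t_log2.subset_genes(conc.concordant_expressed_genes),
        r_log2.subset_genes(conc.concordant_expressed_genes),
    )
    corr_summaries.append(
        summarize_correlations(
            np.diag(corr_conc.to_numpy()), "cross_platform_matching_concordant"
        ).as_row()
    )

    t_rle = rle_normalize(t_log2, "TARGETED")
    r_rle = rle_normalize(r_log2, "REFERENCE")
    rle_out = rle_pipeline_rerun(
        t_rle, r_rle, n_perm=config.n_perm, seed=config.seed,
        dispersion_center=config.dispersion_center,
    )
    rle_pairs = matched_pair_values(rle_out.correlations, cells, cells)
    corr_summaries.append(
        summarize_correlations(rle_pairs["matching"], "rle_matching").as_row()
    )
    corr_summaries.append(
        summarize_correlations(rle_pairs["non_matching"], "rle_non_matching").as_row()
    )

    enrichment = None
    if config.gmt_path is not None:
        gmt = Path(config.gmt_path)
        if gmt.exists():
            symbols = t_log2.symbols if t_log2.symbols is not None else pd.Series(
                t_log2.gene_ids, index=t_log2.gene_ids
            )
            nonconc = set(symbols.reindex(conc.nonconcordant_genes).dropna())
            concg = set(symbols.reindex(conc.concordant_expressed_genes).dropna())
            enrichment = EnrichmentAnalysis(read_gmt(gmt), nonconc, concg).fit(
                min_genes=config.enrichment_min_genes,
                min_frac=config.enrichment_min_frac,
            )
        else:
            import logging

            logging.getLogger(__name__).warning(
                "enrichment skipped: GMT file %s not found", gmt
            )

    counts = conc.counts()
    report.gene_counts.update(
        {
            "n_gated": int(conc.gate.sum()),
            "n_nonconcordant": int(
                counts["nonconcordant_high_targeted"]
                + counts["nonconcordant_high_reference"]
            ),
            "n_concordant_expressed": int(counts["concordant_expressed"]),
            "n_concordant_low_expression": int(counts["concordant_low_expression"]),
        }
    )
    report.tables = {
        "correlation_summaries": corr_summaries,
        "anova_pc1": _att_dict(anova1),
        "permanova_log2": _att_dict(perm_log2),
        "permanova_retained": _att_dict(conc.platform_permanova),
        "permanova_rle": _att_dict(rle_out.permanova),
        "concordance_trace": conc.trace.to_dict(orient="records"),
    }
    report.results = {
        "platform_r2_log2": perm_log2.r2("platform"),
        "platform_r2_retained": conc.platform_permanova.r2("platform"),
        "platform_r2_rle": rle_out.permanova.r2("platform"),
        "dispersion_log2": {"F": disp_log2.F, "p": disp_log2.p},
        "dispersion_rle": {"F": rle_out.dispersion.F, "p": rle_out.dispersion.p},
        "cutoffs": list(conc.cutoffs),
        "percentiles": list(conc.percentiles),
        "average_median_diff": average_median_diff(conc.diff),
        "fold_difference_all": fold_all,
        "fold_difference_concordant": fold_conc,
    }
    if enrichment is not None:
        report.results["enrichment"] = {
            "n_signatures": len(enrichment.table),
            "n_included": int(enrichment.table["included"].sum()),
            "n_significant": len(enrichment.significant(config.fdr_threshold)),
        }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cls = pd.DataFrame(
            {
                "category": conc.classification,
                "mean_delta": conc.diff.gene_mean,
                "mean_abs_delta": conc.diff.gene_mean_abs,
                "passes_gate": conc.gate,
            }
        )
        cls.index.name = "ensembl_id"
        cls.to_csv(out / "classification.tsv", sep="\t")
        conc.trace.to_csv(out / "concordance_trace.tsv", sep="\t", index=False)
        conc.diff.per_cell_line.to_csv(out / "diff_boxplot_stats.tsv", sep="\t")
        corr.to_csv(out / "cross_platform_correlations_log2.tsv", sep="\t")
        rle_out.correlations.to_csv(
            out / "cross_platform_correlations_rle.tsv", sep="\t"
        )
        perm_log2.table.to_csv(out / "permanova_log2.tsv", sep="\t")
        rle_out.permanova.table.to_csv(out / "permanova_rle.tsv", sep="\t")
        pd.DataFrame(corr_summaries).to_csv(
            out / "correlation_summaries.tsv", sep="\t", index=False
        )
        if enrichment is not None:
            enrichment.table.to_csv(out / "enrichment.tsv", sep="\t")
            enrichment.significant(config.fdr_threshold).to_csv(
                out / "enrichment_significant.tsv", sep="\t"
            )
        report.write(out / "run_report.json")

    report.results["_objects"] = {
        "concordance": conc,
        "pca": ord_res,
        "rle": rle_out,
        "enrichment": enrichment,
    }
    return report
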