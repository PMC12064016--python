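# xconcord

Cross-platform baseline gene-expression concordance analysis for targeted
sequencing versus whole-transcriptome RNA profiling.

Targeted whole-transcriptome assays (probe-ligation platforms read out one
location per gene from cell lysates) are increasingly used in place of
conventional RNA-seq. Before data from the two technologies can be pooled or
compared, one needs to know *which genes agree* between platforms and *how
much of the multivariate variance* the platform itself explains. `xconcord`
implements that analysis as a tested, reusable pipeline for bioinformaticians
working with matched expression panels across platforms:

1. **Normalization & harmonization** — probe-to-gene collapse (per-sample
   maximum over a gene's probes), expression-per-million (EPM = CPM or TPM)
   rescaling to 10⁶ per sample, log₂(EPM+1) transform, replicate averaging,
   and intersection of the two platforms' gene universes with re-rescaling.
2. **Replicate QC** — pairwise Pearson correlations within/between
   acquisition phases and across platforms, with 95% t-intervals.
3. **Variance attribution** — PCA (centered, not scaled), sequential
   (Type-I) ANOVA on individual PC scores, and PERMANOVA on Euclidean
   distances with sequential sums of squares
   `SS_k = tr(H_k G) − tr(H_{k−1} G)` on the Gower-centered matrix
   `G = C(−½ D∘D)C`, pseudo-F statistics, permutation p-values, plus a
   multivariate dispersion test (distances to group centers in PCoA space).
4. **Non-concordant gene determination** — per-gene cross-platform
   difference Δ(g,c) = log₂(EPM_T+1) − log₂(EPM_R+1); symmetric percentile
   pairs (10,90), (11,89), … of the Δ distribution are widened until the
   platform factor explains < 10% of the variance (PERMANOVA R²) on the
   retained genes, with an expression gate (mean EPM ≥ 5 on either platform)
   deciding which genes can count as non-concordant at all.
5. **RLE platform correction** — relative log expression as a *ratio*,
   RLE(g,c) = log₂(EPM(g,c)+1) / mean_c′ log₂(EPM(g,c′)+1), computed within
   each platform, which cancels per-gene platform scale factors exactly.
6. **Gene-set concordance enrichment** — per signature, the 2×2 odds ratio
   OR = (a/b)/(c/d) over (in-signature × non-concordant) membership in the
   expressed universe, Fisher exact p, Benjamini–Hochberg FDR, with
   inclusion criteria (≥ 10 genes in the universe covering ≥ 50% of the
   signature).

A synthetic dual-platform generator with planted ground truth (per-gene
platform biases, shared cell-line signatures, replicate noise, library-size
variation, multi-probe genes, unexpressed genes) ships as a first-class
module, so every stage can be validated end to end without any downloads.

## Worked example

Simulate the platform-vs-platform study design (2,000 genes, 12 cell lines,
20% of expressed genes planted with a 2–8 log₂ platform bias) and run the
full comparison:

```python
import xconcord as xc

cfg = xc.SimConfig(seed=7)                      # 2,000 genes, 12 cell lines
probes, ref, ann, truth = xc.generate_dual_platform(cfg)
report = xc.run_tvr(probes, ref, ann, xc.RunConfig(n_perm=999, seed=7))

conc = report.results["_objects"]["concordance"]
print(conc.summary())
```

```
Non-concordant gene determination
  terminated at percentiles (10, 90) after 1 step(s)
  cutoffs: lo=-0.663, hi=0.689 log2(EPM+1)
  expression gate: mean EPM >= 5 on either platform (1567 of 2000 genes pass)
  platform R2 on retained genes: 0.0015
  classification:
    concordant_expressed: 1188
    concordant_low_expression: 433
    nonconcordant_high_targeted: 190
    nonconcordant_high_reference: 189
```

The classification partitions the shared gene universe: 433 genes fail the
expression gate (both platforms agree they are unexpressed), 379 expressed
genes fall outside the averaged percentile cutoffs (split almost evenly
between platform-high and platform-low, as planted), and the rest are
concordant. Before removal the platform factor explained 49% of the
multivariate variance; on the retained genes it explains 0.15%, and after
RLE correction it vanishes entirely:

```python
print("platform R2 (log2):", round(report.results["platform_r2_log2"], 3))
print("platform R2 (RLE): ", round(report.results["platform_r2_rle"], 3))
called, planted = set(conc.nonconcordant_genes), truth.biased_genes
print("planted-gene recall:", round(len(called & planted) / len(planted), 3))
```

```
platform R2 (log2): 0.488
platform R2 (RLE):  0.0
planted-gene recall: 0.997
```

The same analyses are available from the shell:

```sh
xconcord simulate --seed 7 --out sim/
xconcord run-tvr --counts sim/probe_counts.tsv --manifest sim/manifest.tsv \
    --reference-epm sim/reference_epm.tsv --annotation sim/annotation.tsv \
    --seed 7 --out results/
xconcord run-tvt --counts phase1.tsv --counts phase2.tsv \
    --manifest manifest.tsv --annotation annotation.tsv --out results/
```

Real data enter through the same TSV/XLSX readers (`xconcord ingest`,
`xconcord concordance`, `xconcord enrich --gmt sets.gmt ...`); gene-set
collections are read from standard GMT files.

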