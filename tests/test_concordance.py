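import numpy as np
import pandas as pd
import pytest
from scipy import stats

from xconcord import (
    ExpressionMatrix,
    SimConfig,
    average_median_diff,
    collapse_probes,
    diff_profile,
    epm_normalize,
    expression_gate,
    find_nonconcordant,
    fold_difference_summary,
    generate_dual_platform,
    intersect_and_rescale,
    log2p1,
    percentile_cutoffs,
    threshold_counts,
)
from xconcord.concordance import CATEGORIES, ConcordanceError, ConcordanceModel


def _lm(df):
    return ExpressionMatrix(pd.DataFrame(df, dtype=float), "log2epm1")


def _em(df):
    return ExpressionMatrix(pd.DataFrame(df, dtype=float), "epm")


def test_identical_matrices_zero_deltas():
    df = {"c1": [1.0, 2, 3], "c2": [4.0, 5, 6]}
    dp = diff_profile(_lm(df), _lm(df))
    assert (dp.delta.to_numpy() == 0).all()
    assert (dp.per_cell_line["iqr"] == 0).all()


def test_constant_shift_delta():
    t = {"c1": [3.0, 4, 5], "c2": [6.0, 7, 8]}
    r = {"c1": [1.0, 2, 3], "c2": [4.0, 5, 6]}
    dp = diff_profile(_lm(t), _lm(r))
    assert (dp.delta.to_numpy() == 2).all()
    assert (dp.per_cell_line["median"] == 2).all()
    assert (dp.per_cell_line["iqr"] == 0).all()


def test_linear_interpolation_quantiles():
    dp = diff_profile(_lm({"c": [1.0, 2, 3, 4, 5]}), _lm({"c": [0.0] * 5}))
    row = dp.per_cell_line.loc["c"]
    assert row["median"] == 3
    assert row["iqr"] == 2          # q3=4, q1=2 under linear interpolation
    assert dp.gene_mean.tolist() == [1, 2, 3, 4, 5]


def test_shape_mismatch_rejected():
    with pytest.raises(ValueError, match="shape"):
        diff_profile(_lm({"c": [1.0, 2]}), _lm({"c": [1.0, 2], "d": [1.0, 2]}))


def test_average_median_diff_arithmetic():
    t = {"c1": [0.0, -0.1, -0.2], "c2": [0.0, 0.02, 0.04]}
    r = {"c1": [0.1, 0.0, -0.1], "c2": [-0.02, 0.0, 0.02]}
    dp = diff_profile(_lm(t), _lm(r))
    # per-cell-line medians are -0.1 and 0.02
    assert average_median_diff(dp) == pytest.approx(-0.04)


def test_expression_gate_and_or_semantics():
    genes = ["below_both", "ref_only", "both"]
    t = _em(pd.DataFrame({"c1": [4.9, 0.0, 9.0]}, index=genes))
    r = _em(pd.DataFrame({"c1": [4.9, 5.0, 9.0]}, index=genes))
    gate = expression_gate(t, r, 5.0)
    assert gate.tolist() == [False, True, True]


def test_percentile_cutoffs_single_distribution():
    vals = np.arange(1.0, 101.0)  # percentiles of 1..100 are transparent
    dp = diff_profile(
        _lm({"c1": vals, "c2": vals}), _lm({"c1": np.zeros(100), "c2": np.zeros(100)})
    )
    lo, hi = percentile_cutoffs(dp, 10, 90)
    assert lo == pytest.approx(np.percentile(vals, 10))
    assert hi == pytest.approx(np.percentile(vals, 90))


def test_percentile_cutoffs_average_across_cell_lines(rng):
    # shift draws so the 13th percentiles are exactly -2.0 and -2.18
    d1 = rng.normal(0, 0.5, 500)
    d1 += -2.0 - np.percentile(d1, 13)
    d2 = rng.normal(0, 0.5, 500)
    d2 += -2.18 - np.percentile(d2, 13)
    dp = diff_profile(
        _lm({"c1": d1, "c2": d2}), _lm({"c1": np.zeros(500), "c2": np.zeros(500)})
    )
    lo, _ = percentile_cutoffs(dp, 13, 87)
    assert lo == pytest.approx(-2.09, abs=1e-9)


def test_percentile_cutoffs_match_normal_quantiles(rng):
    draws = {f"c{i}": rng.normal(0, 1, 50_000) for i in range(4)}
    dp = diff_profile(_lm(draws), _lm({k: np.zeros(50_000) for k in draws}))
    lo, hi = percentile_cutoffs(dp, 10, 90)
    z = stats.norm.ppf(0.9)
    se = np.sqrt(0.1 * 0.9 / 50_000) / stats.norm.pdf(z) / np.sqrt(4)
    assert lo == pytest.approx(-z, abs=3 * se)
    assert hi == pytest.approx(z, abs=3 * se)


def test_percentile_cutoffs_invalid_pair_rejected():
    dp = diff_profile(_lm({"c": [1.0, 2]}), _lm({"c": [0.0, 0]}))
    with pytest.raises(ValueError):
        percentile_cutoffs(dp, 90, 10)


def _sim_pipeline(cfg):
    probes, ref, ann, truth = generate_dual_platform(cfg)
    from xconcord import average_replicates

    t_epm = epm_normalize(collapse_probes(probes))
    t_avg, _ = average_replicates(t_epm, ann.subset(t_epm.sample_ids), by=("cell_line",))
    r = epm_normalize(ref)
    r = r.with_data(r.data.set_axis([c[2:] for c in r.sample_ids], axis=1), "epm")
    te, re_, _ = intersect_and_rescale(t_avg, r)
    return log2p1(te), log2p1(re_), te, re_, truth


def test_zero_bias_terminates_at_first_pair():
    cfg = SimConfig(
        n_genes=600,
        n_cell_lines=6,
        frac_platform_biased=0.0,
        replicate_noise_sd=0.05,
        seed=21,
    )
    tl, rl, te, re_, _ = _sim_pipeline(cfg)
    res = find_nonconcordant(tl, rl, te, re_, n_perm=49, seed=0)
    assert len(res.trace) == 1
    assert res.percentiles == (10.0, 90.0)
    assert res.trace["platform_r2"].iloc[0] < 0.10


def test_planted_bias_recovered_with_high_recall_precision():
    cfg = SimConfig(n_genes=1000, n_cell_lines=8, seed=22)
    tl, rl, te, re_, truth = _sim_pipeline(cfg)
    res = find_nonconcordant(tl, rl, te, re_, n_perm=49, seed=0)
    called = set(res.nonconcordant_genes)
    planted = truth.biased_genes
    recall = len(called & planted) / len(planted)
    precision = len(called & planted) / len(called)
    assert recall >= 0.9
    assert precision >= 0.8


def test_classification_partitions_gene_universe():
    cfg = SimConfig(n_genes=500, n_cell_lines=5, seed=23)
    tl, rl, te, re_, _ = _sim_pipeline(cfg)
    res = find_nonconcordant(tl, rl, te, re_, n_perm=9, seed=0)
    counts = res.counts()
    assert counts.sum() == len(tl.gene_ids)
    assert set(res.classification.unique()) <= set(CATEGORIES)
    # non-concordant genes all pass the expression gate
    assert res.gate.loc[res.nonconcordant_genes].all()


def test_widening_percentiles_monotone_removal():
    cfg = SimConfig(n_genes=500, n_cell_lines=5, seed=24)
    tl, rl, te, re_, _ = _sim_pipeline(cfg)
    model = ConcordanceModel(tl, rl, te, re_)
    removed = []
    for p in (10, 15, 20, 25):
        lo, hi = percentile_cutoffs(model.diff, p, 100 - p)
        out = model.gate & ((model.diff.gene_mean < lo) | (model.diff.gene_mean > hi))
        removed.append(int(out.sum()))
    assert removed == sorted(removed, reverse=True) or removed == sorted(removed)
    # widening the tails (larger p) removes at least as many genes
    assert all(b >= a for a, b in zip(removed, removed[1:]))


def test_trace_reproducibility():
    cfg = SimConfig(n_genes=400, n_cell_lines=5, seed=25)
    tl, rl, te, re_, _ = _sim_pipeline(cfg)
    r1 = find_nonconcordant(tl, rl, te, re_, n_perm=19, seed=3)
    r2 = find_nonconcordant(tl, rl, te, re_, n_perm=19, seed=3)
    assert r1.trace.equals(r2.trace)
    assert r1.classification.equals(r2.classification)
    assert r1.platform_permanova.p("platform") == r2.platform_permanova.p("platform")


def test_unreachable_target_raises_with_trace():
    # a global platform shift on every gene cannot be removed gene-wise
    genes = [f"g{i}" for i in range(60)]
    rng = np.random.default_rng(0)
    base = rng.uniform(4, 10, (60, 4))
    t = pd.DataFrame(base + 3.0, index=genes, columns=list("abcd"))
    r = pd.DataFrame(base, index=genes, columns=list("abcd"))
    epm = pd.DataFrame(np.full((60, 4), 100.0), index=genes, columns=list("abcd"))
    with pytest.raises(ConcordanceError) as exc:
        find_nonconcordant(_lm(t), _lm(r), _em(epm), _em(epm), n_perm=0)
    assert len(exc.value.trace) == 40


def test_fold_difference_identity_and_unit_shift():
    em = _em({"c": [100.0, 200.0]})
    out = fold_difference_summary(em, em)
    assert out["mean_fold"] == 1.0
    t = _lm({"c": [3.0, 5.0]})
    # build EPM pairs whose log2(EPM+1) differ by exactly +-1
    te = _em(pd.DataFrame({"c": [2 ** 4 - 1, 2 ** 5 - 1]}, index=["g1", "g2"]))
    re_ = _em(pd.DataFrame({"c": [2 ** 3 - 1, 2 ** 6 - 1]}, index=["g1", "g2"]))
    out = fold_difference_summary(te, re_)
    assert out["mean_fold"] == pytest.approx(2.0)


def test_fold_difference_matches_folded_normal(rng):
    # |Δ| ~ folded N(0, σ): E[2^|Δ|] = 2 exp(c²σ²/2) Φ(cσ), c = ln 2
    sigma = 0.3
    n = 40_000
    base = rng.uniform(5, 10, n)
    delta = rng.normal(0, sigma, n)
    te = _em(pd.DataFrame({"c": np.exp2(base + delta) - 1}))
    re_ = _em(pd.DataFrame({"c": np.exp2(base) - 1}))
    # EPM normalization rescales; recompute delta actually realized
    tlog = np.log2(te.data["c"] + 1)
    rlog = np.log2(re_.data["c"] + 1)
    realized = np.abs(tlog - rlog)
    out = fold_difference_summary(te, re_)
    expected = float(np.exp2(realized).mean())
    c = np.log(2)
    closed = 2 * np.exp(c**2 * sigma**2 / 2) * stats.norm.cdf(c * sigma)
    se = np.exp2(realized).std(ddof=1) / np.sqrt(n)
    assert out["mean_fold"] == pytest.approx(expected, abs=1e-9)
    assert abs(out["mean_fold"] - closed) < 3 * se + 0.01


def test_threshold_counts_brute_force(rng):
    vals = rng.uniform(0, 8, 300)
    dp = diff_profile(
        _lm({"c": vals}), _lm({"c": np.zeros(300)})
    )
    out = threshold_counts(dp, [0, 2, 5, 7])
    assert out["n_genes"].iloc[0] == 300
    for _, row in out.iterrows():
        assert row["n_genes"] == int((np.abs(vals) > row["threshold"]).sum())
    assert (out["n_genes"].diff().dropna() <= 0).all()


def test_threshold_counts_with_gene_lists():
    dp = diff_profile(
        _lm(pd.DataFrame({"c": [6.0, 7.5, 1.0]}, index=["a", "b", "c"])),
        _lm(pd.DataFrame({"c": [0.0, 0, 0]}, index=["a", "b", "c"])),
    )
    out = threshold_counts(dp, [5, 7], {"fam": {"a", "c"}})
    assert out["n_genes"].tolist() == [2, 1]
    assert out["n_in_fam"].tolist() == [1, 0]
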