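"""Variance-attribution oracles: hand-computed sequential sums of squares,
exhaustive permutation distributions, centroid decompositions, and an
independent reference implementation (scikit-bio)."""

import itertools

import numpy as np
import pandas as pd
import pytest

from xconcord import (
    ComponentAnova,
    DispersionTest,
    Permanova,
    anova_on_component,
    dispersion_test,
    euclidean_distance,
    pca,
    permanova,
)
from xconcord.permanova import _nested_projectors, _sequential_ss
from xconcord.ordination import gower_center


# ---------------------------------------------------------------- ANOVA on PCs

def test_single_factor_perfect_separation_r2_one():
    y = pd.Series([1.0, 1.0, 5.0, 5.0])
    f = pd.DataFrame({"g": ["a", "a", "b", "b"]})
    att = anova_on_component(y, f)
    assert att.r2("g") == pytest.approx(1.0)


def test_factor_orthogonal_to_response_r2_zero():
    y = pd.Series([1.0, 2.0, 1.0, 2.0])
    f = pd.DataFrame({"g": ["a", "a", "b", "b"]})
    att = anova_on_component(y, f)
    assert att.r2("g") == pytest.approx(0.0, abs=1e-10)


def test_hand_computed_sequential_ss():
    """y=(1,2,3,4), A=(a,a,b,b), B=(x,y,x,y): SS_total=5, SS_A=4 (group means
    1.5/3.5), SS_B=1 (residuals ∓0.5 split exactly by B), residual 0."""
    y = pd.Series([1.0, 2.0, 3.0, 4.0])
    f = pd.DataFrame({"A": ["a", "a", "b", "b"], "B": ["x", "y", "x", "y"]})
    att = ComponentAnova(y, f, ["A", "B"]).fit()
    assert att.table.loc["A", "SS"] == pytest.approx(4.0, abs=1e-10)
    assert att.table.loc["B", "SS"] == pytest.approx(1.0, abs=1e-10)
    assert att.table.loc["Total", "SS"] == pytest.approx(5.0, abs=1e-10)
    assert att.table.loc["Residual", "SS"] == pytest.approx(0.0, abs=1e-10)


def test_one_way_anova_identity_ssb_plus_ssw(rng):
    y = pd.Series(rng.normal(0, 1, 12))
    f = pd.DataFrame({"g": list("aaabbbcccddd")})
    att = anova_on_component(y, f)
    ssb = sum(
        len(v) * (v.mean() - y.mean()) ** 2 for _, v in y.groupby(f["g"].to_numpy())
    )
    ssw = sum(((v - v.mean()) ** 2).sum() for _, v in y.groupby(f["g"].to_numpy()))
    assert att.table.loc["g", "SS"] == pytest.approx(ssb, abs=1e-10)
    assert att.table.loc["Residual", "SS"] == pytest.approx(ssw, abs=1e-10)
    assert att.table.loc["Total", "SS"] == pytest.approx(ssb + ssw, abs=1e-10)


def test_matches_statsmodels_sequential_anova(rng):
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    df = pd.DataFrame(
        {
            "y": rng.normal(0, 1, 18),
            "A": list("abc") * 6,
            "B": ["u"] * 9 + ["v"] * 9,
        }
    )
    att = ComponentAnova(df["y"], df[["A", "B"]], ["A", "B"]).fit()
    ref = sm.stats.anova_lm(ols("y ~ A + B", df).fit(), typ=1)
    assert att.table.loc["A", "SS"] == pytest.approx(ref.loc["A", "sum_sq"], abs=1e-10)
    assert att.table.loc["B", "SS"] == pytest.approx(ref.loc["B", "sum_sq"], abs=1e-10)
    assert att.p("A") == pytest.approx(ref.loc["A", "PR(>F)"], abs=1e-10)


def test_saturated_model_flags_f_and_p():
    y = pd.Series([1.0, 2.0])
    f = pd.DataFrame({"g": ["a", "b"]})
    att = anova_on_component(y, f)
    assert att.r2("g") == pytest.approx(1.0)
    assert np.isnan(att.table.loc["g", "F"])
    assert np.isnan(att.p("g"))


# ----------------------------------------------------------------- PERMANOVA

def _two_group_data(rng, n_per=3, shift=2.0, dim=4):
    X = rng.normal(0, 1, (2 * n_per, dim))
    X[n_per:] += shift
    labels = ["a"] * n_per + ["b"] * n_per
    D = euclidean_distance(pd.DataFrame(X))
    return X, pd.DataFrame({"g": labels}), D


def test_identical_groups_zero_r2_p_near_one(rng):
    pts = rng.normal(0, 1, (3, 4))
    X = np.vstack([pts, pts])  # identical multisets of points
    D = euclidean_distance(pd.DataFrame(X))
    att = permanova(D, pd.DataFrame({"g": list("aaabbb")}), n_perm=199, seed=0)
    assert att.r2("g") == pytest.approx(0.0, abs=1e-8)  # coincident centroids
    assert att.p("g") > 0.5


def test_r2_matches_centroid_decomposition(rng):
    X, f, D = _two_group_data(rng)
    att = permanova(D, f, n_perm=0)
    grand = X.mean(axis=0)
    sst = ((X - grand) ** 2).sum()
    ssw = sum(
        ((X[np.asarray(f["g"]) == g] - X[np.asarray(f["g"]) == g].mean(axis=0)) ** 2).sum()
        for g in ("a", "b")
    )
    assert att.r2("g") == pytest.approx(1 - ssw / sst, abs=1e-8)


def test_r2_equals_eigenvalue_weighted_pc_anova(rng):
    X, f, D = _two_group_data(rng)
    att = permanova(D, f, n_perm=0)
    res = pca(pd.DataFrame(X))
    weighted = sum(
        anova_on_component(res.scores[c], f).r2("g") * res.eigenvalues[i]
        for i, c in enumerate(res.scores.columns)
    ) / res.eigenvalues.sum()
    assert att.r2("g") == pytest.approx(weighted, abs=1e-8)


def test_permutation_p_within_mc_error_of_exhaustive(rng):
    X, f, D = _two_group_data(rng, n_per=3, shift=1.0)
    att = permanova(D, f, n_perm=999, seed=5)

    # exhaustive oracle over all 720 row permutations
    G = gower_center(D)
    hats, dfs = _nested_projectors(f, ["g"])
    ss, ss_total = _sequential_ss(G, hats)
    df_res = 6 - 1 - dfs[0]
    F_obs = (ss[0] / dfs[0]) / ((ss_total - ss[0]) / df_res)
    count = 0
    nperm = 0
    for perm in itertools.permutations(range(6)):
        Gp = G[np.ix_(perm, perm)]
        ssp, _ = _sequential_ss(Gp, hats)
        Fp = (ssp[0] / dfs[0]) / ((ss_total - ssp[0]) / df_res)
        count += Fp >= F_obs - 1e-12
        nperm += 1
    p_exact = count / nperm
    mc_sd = np.sqrt(p_exact * (1 - p_exact) / 999)
    assert abs(att.p("g") - p_exact) <= 2 * mc_sd + 2 / 1000


def test_r2_is_permutation_free(rng):
    X, f, D = _two_group_data(rng)
    a = permanova(D, f, n_perm=99, seed=1)
    b = permanova(D, f, n_perm=499, seed=999)
    assert a.r2("g") == b.r2("g")
    assert a.table.loc["g", "F"] == b.table.loc["g", "F"]


def test_matches_skbio_permanova(rng):
    from skbio import DistanceMatrix
    from skbio.stats.distance import permanova as skbio_permanova

    X, f, D = _two_group_data(rng, n_per=4, shift=1.5)
    att = permanova(D, f, n_perm=0)
    ref = skbio_permanova(
        DistanceMatrix(D.to_numpy()), f["g"].to_numpy(), permutations=0
    )
    assert att.table.loc["g", "F"] == pytest.approx(ref["test statistic"], abs=1e-8)


def test_sequential_two_factor_ss_adds_to_total(rng):
    X = rng.normal(0, 1, (12, 5))
    f = pd.DataFrame({"A": list("aabb") * 3, "B": ["x", "y"] * 6})
    D = euclidean_distance(pd.DataFrame(X))
    att = permanova(D, f, ["A", "B"], n_perm=0)
    t = att.table
    assert t.loc["A", "SS"] + t.loc["B", "SS"] + t.loc["Residual", "SS"] == pytest.approx(
        t.loc["Total", "SS"], abs=1e-8
    )
    assert 0 <= att.r2("A") <= 1 and 0 <= att.r2("B") <= 1


def test_single_level_term_rejected():
    D = euclidean_distance(pd.DataFrame(np.eye(4)))
    with pytest.raises(ValueError, match="levels"):
        permanova(D, pd.DataFrame({"g": ["a"] * 4}), n_perm=0)


# ------------------------------------------------------------ dispersion test

def test_mirror_image_groups_equal_dispersion(rng):
    pts = rng.normal(0, 1, (5, 3))
    X = np.vstack([pts, -pts + 10.0])  # identical shape, different location
    D = euclidean_distance(pd.DataFrame(X))
    res = dispersion_test(D, pd.Series(["a"] * 5 + ["b"] * 5))
    assert res.F == pytest.approx(0.0, abs=1e-12)
    assert res.p == pytest.approx(1.0, abs=1e-9)


def test_scaled_group_has_proportional_dispersion(rng):
    pts = rng.normal(0, 1, (10, 3))
    ptsB = pts * 3.0 + 20.0  # scaled x3 about its centroid, shifted away
    X = np.vstack([pts - pts.mean(axis=0), ptsB - ptsB.mean(axis=0) + 20.0])
    D = euclidean_distance(pd.DataFrame(X))
    res = dispersion_test(D, pd.Series(["a"] * 10 + ["b"] * 10))
    ratio = res.group_means["b"] / res.group_means["a"]
    assert ratio == pytest.approx(3.0, abs=1e-6)
    assert res.p < 0.01


def test_coincident_points_flagged_undefined():
    X = np.zeros((6, 2))
    D = euclidean_distance(pd.DataFrame(X))
    res = dispersion_test(D, pd.Series(["a"] * 3 + ["b"] * 3))
    assert np.allclose(res.distances, 0.0)
    assert np.isnan(res.F) and np.isnan(res.p)


def test_singleton_group_flagged(rng):
    X = rng.normal(0, 1, (5, 2))
    D = euclidean_distance(pd.DataFrame(X))
    res = dispersion_test(D, pd.Series(["a", "a", "a", "a", "b"]))
    assert res.singleton_groups == ["b"]
    assert res.distances.iloc[4] == pytest.approx(0.0)


def test_matches_vegan_style_centroid_distances(rng):
    """Distances to group centroid via PCoA embedding equal direct Euclidean
    distances to the centroid when D is Euclidean."""
    X = rng.normal(0, 1, (8, 4))
    g = pd.Series(["a"] * 4 + ["b"] * 4)
    D = euclidean_distance(pd.DataFrame(X))
    res = dispersion_test(D, g)
    for lab in ("a", "b"):
        rows = np.asarray(g) == lab
        c = X[rows].mean(axis=0)
        direct = np.linalg.norm(X[rows] - c, axis=1)
        assert np.allclose(np.sort(res.distances[rows.nonzero()[0]]),
                           np.sort(direct), atol=1e-8)


def test_spatial_median_center_runs(rng):
    X = rng.normal(0, 1, (10, 3))
    D = euclidean_distance(pd.DataFrame(X))
    res = dispersion_test(D, pd.Series(["a"] * 5 + ["b"] * 5), center="spatial_median")
    assert res.center == "spatial_median"
    assert (res.distances >= 0).all()
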