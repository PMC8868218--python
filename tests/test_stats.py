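"""Distribution routing, paired/repeated comparisons, slope parallelism."""

import numpy as np
import pandas as pd
import pytest

from equitherm.stats import (
    SeriesPair,
    compare_bs,
    compare_re,
    fit_parallelism,
    gg_epsilon,
    rescale_to,
    route_test,
    select_related,
)


# ------------------------------------------------------------ routing ----

def test_routing_normal_vs_two_point(rng):
    gaussian = rng.standard_normal(12)
    assert route_test(gaussian) == "gaussian"
    two_point = np.array([0.0, 1.0] * 6)
    assert route_test(two_point) == "non_gaussian"


def test_routing_matches_shapiro_reference(rng):
    from scipy.stats import shapiro

    for _ in range(10):
        x = rng.standard_normal(12) + rng.exponential(1, 12) * rng.integers(0, 2)
        expected = "gaussian" if shapiro(x).pvalue >= 0.05 else "non_gaussian"
        assert route_test(x) == expected


def test_routing_degenerate_and_short_samples():
    assert route_test(np.full(10, 3.0)) == "non_gaussian"
    with pytest.raises(ValueError):
        route_test([1.0, 2.0])


# --------------------------------------------------------- compare_bs ----

def test_identical_pairs_give_p_one():
    x = np.arange(12.0)
    assert compare_bs(x, x, "gaussian") == 1.0


def test_large_shift_is_significant(rng):
    before = rng.standard_normal(12)
    after = before + 10.0 + 1e-6 * rng.standard_normal(12)
    assert compare_bs(before, after, "gaussian") < 1e-3
    assert compare_bs(before, after, "non_gaussian") < 5e-3


def test_compare_bs_validation(rng):
    with pytest.raises(ValueError):
        compare_bs(np.ones(5), np.ones(6), "gaussian")
    x = np.arange(8.0)
    with pytest.raises(ValueError):
        compare_bs(x, x, "non_gaussian")  # all-zero differences


def test_compare_bs_matches_scipy_reference(rng):
    from scipy.stats import ttest_rel, wilcoxon

    before = rng.standard_normal(12)
    after = before + rng.standard_normal(12) * 0.5 + 0.3
    assert compare_bs(before, after, "gaussian") == pytest.approx(
        ttest_rel(after, before).pvalue)
    assert compare_bs(before, after, "non_gaussian") == pytest.approx(
        wilcoxon(after, before).pvalue)


# --------------------------------------------------------- compare_re ----

def test_identical_columns_omnibus_p_one(rng):
    col = rng.standard_normal(12)
    matrix = np.tile(col[:, None], (1, 6))
    for route in ("gaussian", "non_gaussian"):
        out = compare_re(matrix, route)
        assert out["omnibus_p"] == 1.0
        assert all(p == 1.0 for p in out["pairwise"].values())


def test_shifted_column_detected(rng):
    matrix = rng.standard_normal((12, 6))
    matrix[:, 5] += 8.0
    for route in ("gaussian", "non_gaussian"):
        out = compare_re(matrix, route)
        assert out["omnibus_p"] < 0.01, route
        assert out["pairwise"][(1, 6)] < 0.05, route


def test_gg_epsilon_bounds(rng):
    for _ in range(10):
        matrix = rng.standard_normal((10, 5))
        eps = gg_epsilon(matrix)
        assert 1 / 4 <= eps <= 1.0


def test_rm_anova_matches_pingouin(rng):
    pg = pytest.importorskip("pingouin")
    matrix = rng.standard_normal((10, 4)) + np.array([0, 0.2, 0.5, 0.1])
    out = compare_re(matrix, "gaussian")
    long = pd.DataFrame({
        "y": matrix.ravel(),
        "subject": np.repeat(np.arange(10), 4),
        "cond": np.tile(np.arange(4), 10),
    })
    aov = pg.rm_anova(data=long, dv="y", within="cond", subject="subject",
                      correction=True)
    assert out["omnibus_p"] == pytest.approx(
        float(aov["p_GG_corr"].iloc[0]), rel=1e-6)
    assert out["epsilon"] == pytest.approx(float(aov["eps"].iloc[0]), rel=1e-6)


def test_friedman_matches_scipy(rng):
    from scipy.stats import friedmanchisquare

    matrix = rng.standard_normal((12, 5))
    out = compare_re(matrix, "non_gaussian")
    expected = friedmanchisquare(*[matrix[:, j] for j in range(5)]).pvalue
    assert out["omnibus_p"] == pytest.approx(expected)


def test_missing_cells_rejected(rng):
    matrix = rng.standard_normal((8, 4))
    matrix[2, 1] = np.nan
    with pytest.raises(ValueError):
        compare_re(matrix, "gaussian")


# ----------------------------------------------------- fit_parallelism ----

def _pair(x, ya, yb):
    return SeriesPair(x, ya, x, yb)


def test_identical_groups_f_zero_pooled_ols_slope(rng):
    x = np.tile(np.arange(1.0, 7.0), 12)
    y = 3.0 + 2.0 * x + rng.standard_normal(x.size)
    res = fit_parallelism(_pair(x, y, y))
    assert res.p_slope_equal == 1.0
    xm = x - x.mean()
    ols_slope = (xm @ (y - y.mean())) / (xm @ xm)
    assert res.pooled_slope == pytest.approx(ols_slope, rel=1e-12)


def test_parallel_lines_pool_slope_but_not_intercept(rng):
    x = np.tile(np.arange(1.0, 7.0), 12)
    ya = 2.0 * x + 0.1 * rng.standard_normal(x.size)
    yb = 2.0 * x + 5.0 + 0.1 * rng.standard_normal(x.size)
    res = fit_parallelism(_pair(x, ya, yb))
    assert res.p_slope_equal > 0.05
    assert res.pooled_slope == pytest.approx(2.0, abs=0.05)
    assert res.p_intercept_equal < 1e-6
    assert res.pooled_intercept is None
    assert res.related


def test_opposite_slopes_not_pooled(rng):
    x = np.tile(np.arange(1.0, 7.0), 6)
    ya = 2.0 * x + 0.1 * rng.standard_normal(x.size)
    yb = -2.0 * x + 0.1 * rng.standard_normal(x.size)
    res = fit_parallelism(_pair(x, ya, yb))
    assert res.p_slope_equal < 1e-6
    assert res.pooled_slope is None
    assert not res.related


def test_slope_equality_p_symmetric_in_group_order(rng):
    x = np.tile(np.arange(1.0, 7.0), 4)
    ya = 1.0 + 1.5 * x + rng.standard_normal(x.size)
    yb = 2.0 + 1.8 * x + rng.standard_normal(x.size)
    res_ab = fit_parallelism(SeriesPair(x, ya, x, yb))
    res_ba = fit_parallelism(SeriesPair(x, yb, x, ya))
    assert res_ab.p_slope_equal == pytest.approx(res_ba.p_slope_equal,
                                                 rel=1e-12)


def test_slope_equality_matches_statsmodels_interaction_f(rng):
    sm = pytest.importorskip("statsmodels.api")
    x = np.tile(np.arange(1.0, 7.0), 5)
    ya = 1.0 + 1.2 * x + rng.standard_normal(x.size)
    yb = 0.5 + 1.6 * x + rng.standard_normal(x.size)
    res = fit_parallelism(_pair(x, ya, yb))
    g = np.concatenate([np.zeros(x.size), np.ones(x.size)])
    xx = np.concatenate([x, x])
    yy = np.concatenate([ya, yb])
    X = np.column_stack([np.ones(2 * x.size), g, xx, g * xx])
    fit = sm.OLS(yy, X).fit()
    # t-test on the interaction term == extra-SS F-test on slope equality
    assert res.p_slope_equal == pytest.approx(fit.pvalues[3], rel=1e-9)


def test_degenerate_x_rejected():
    with pytest.raises(ValueError):
        SeriesPair(np.ones(6), np.arange(6.0), np.arange(6.0), np.arange(6.0))


def test_rescale_matches_moments(rng):
    f = rng.uniform(0, 1, 72)
    b = rng.normal(250, 60, 72)
    scaled = rescale_to(f, b)
    assert scaled.mean() == pytest.approx(b.mean())
    assert scaled.std(ddof=1) == pytest.approx(b.std(ddof=1))
    assert rescale_to(np.full(10, 3.0), b) == pytest.approx(b.mean())


# ------------------------------------------------------ select_related ----

def _mock_tables(rng, coupled=True):
    """Small feature + biomarker tables with one coupled feature."""
    horses, res = range(1, 13), range(1, 7)
    bio_rows, feat_rows = [], []
    for h in horses:
        for r in res:
            load = r + 0.3 * rng.standard_normal()
            bio_rows.append({"horse": h, "re": r, "bs": 1,
                             "CPK": 180 + 18 * load + 4 * rng.standard_normal()})
            coupled_val = (10 * load if coupled else 10) \
                + rng.standard_normal()
            for roi in (1, 2):
                feat_rows.append({
                    "horse": h, "re": r, "bs": 1, "roi": roi,
                    "channel": "RGB.R", "normalization": "none",
                    "feature": "HS.HistVariance",
                    "value": coupled_val if roi == 1
                    else rng.standard_normal(),
                })
    return pd.DataFrame(feat_rows), pd.DataFrame(bio_rows)


def test_select_related_flags_coupled_feature(rng):
    features, biomarkers = _mock_tables(rng, coupled=True)
    sel = select_related(features, biomarkers, targets=("CPK",))
    assert len(sel) == 2  # one feature x two ROIs
    by_roi = sel.set_index("roi")
    assert bool(by_roi.loc[1, "related"])
    assert not bool(by_roi.loc[2, "related"])


def test_selection_false_positive_rate_under_null():
    """With no engineered coupling the selection procedure flags pairs at
    about the nominal rate (parallel slopes arise freely, but a jointly
    non-zero slope is a ~5% event)."""
    from equitherm.experiments import null_selection_rate

    rate = null_selection_rate(n_studies=25, seed=77)
    assert rate <= 0.10


def test_select_related_counts_per_color_model():
    # 88 features x 3 RGB components x 2 normalization states = 528 pairs
    rng = np.random.default_rng(0)
    rows = []
    for comp in ("R", "G", "B"):
        for norm, letter in (("none", comp), ("minmax", comp.lower())):
            for feat in range(88):
                for h in range(1, 5):
                    for r in range(1, 7):
                        rows.append({
                            "horse": h, "re": r, "bs": 1, "roi": 1,
                            "channel": f"RGB.{letter}",
                            "normalization": norm,
                            "feature": f"F{feat:02d}",
                            "value": rng.standard_normal(),
                        })
    features = pd.DataFrame(rows)
    bio = pd.DataFrame([
        {"horse": h, "re": r, "bs": 1, "CPK": rng.standard_normal()}
        for h in range(1, 5) for r in range(1, 7)
    ])
    sel = select_related(features, bio, targets=("CPK",))
    assert len(sel) == 528
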