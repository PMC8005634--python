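"""Concordance and dispersion statistics against independent oracles."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import moralconcord as mc


def naive_ccc(x, y):
    """Independent two-pass evaluation of the concordance formula."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sx = sum((v - mx) ** 2 for v in x) / n
    sy = sum((v - my) ** 2 for v in y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y)) / n
    denom = sx + sy + (mx - my) ** 2
    return 1.0 if denom == 0 else 2 * sxy / denom


def naive_pearson(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sx = math.sqrt(sum((v - mx) ** 2 for v in x) / n)
    sy = math.sqrt(sum((v - my) ** 2 for v in y) / n)
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y)) / n
    return sxy / (sx * sy)


@pytest.mark.parametrize(
    "x, y, expected",
    [
        ((0.1, 0.5, 0.9), (0.1, 0.5, 0.9), 1.0),  # identity
        ((0.0, 1.0), (1.0, 0.0), -1.0),  # perfect reversal
        ((0.2, 0.4, 0.6), (0.3, 0.4, 0.5), 0.8),  # hand-evaluated formula
        ((0.4, 0.4, 0.4), (0.4, 0.4, 0.4), 1.0),  # equal constants convention
        ((0.4, 0.4, 0.4), (0.6, 0.6, 0.6), 0.0),  # unequal constants convention
    ],
)
def test_ccc_known_values(x, y, expected):
    assert mc.ccc(x, y) == pytest.approx(expected, abs=1e-12)


def test_pearson_of_affine_relation_is_one():
    assert mc.pearson((0.2, 0.4, 0.6), (0.3, 0.4, 0.5)) == pytest.approx(1.0)


def test_pearson_of_independent_noise_is_small():
    rng = np.random.default_rng(0)
    x, y = rng.standard_normal(10_000), rng.standard_normal(10_000)
    assert abs(mc.pearson(x, y)) < 0.05


def test_pearson_constant_vector_flagged():
    with pytest.warns(UserWarning, match="constant"):
        assert math.isnan(mc.pearson((1.0, 1.0), (0.0, 1.0)))


def test_ccc_and_pearson_match_naive_oracle_on_fuzzed_instances():
    rng = np.random.default_rng(12345)
    worst = 0.0
    for _ in range(1000):
        n = int(rng.integers(2, 200))
        x = rng.random(n)
        y = rng.random(n)
        c = mc.ccc(x, y)
        worst = max(worst, abs(c - naive_ccc(list(x), list(y))))
        if np.ptp(x) > 0 and np.ptp(y) > 0:
            r = mc.pearson(x, y)
            worst = max(worst, abs(r - naive_pearson(list(x), list(y))))
            assert abs(c) <= abs(r) + 1e-12
        assert -1.0 - 1e-12 <= c <= 1.0 + 1e-12
    assert worst < 1e-12


vectors = st.integers(2, 30).flatmap(
    lambda n: st.tuples(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=n, max_size=n),
        st.lists(st.floats(0, 1, allow_nan=False), min_size=n, max_size=n),
    )
)


@given(vectors)
def test_ccc_symmetric_and_bounded(xy):
    x, y = xy
    c = mc.ccc(x, y)
    assert -1.0 - 1e-9 <= c <= 1.0 + 1e-9
    assert mc.ccc(y, x) == pytest.approx(c, abs=1e-12)


@given(vectors, st.permutations(range(8)))
def test_ccc_invariant_under_joint_permutation(xy, perm_source):
    x, y = xy
    idx = sorted(range(len(x)), key=lambda i: perm_source[i % 8] * len(x) + i)
    xp = [x[i] for i in idx]
    yp = [y[i] for i in idx]
    assert mc.ccc(xp, yp) == pytest.approx(mc.ccc(x, y), abs=1e-12)


def test_ccc_decreases_with_location_shift():
    x = np.array([0.1, 0.3, 0.5, 0.7])
    vals = [mc.ccc(x, x + c) for c in (0.0, 0.05, 0.1, 0.2)]
    assert all(a > b for a, b in zip(vals, vals[1:]))


def test_ci_contains_point_estimate_and_narrows_with_n():
    rng = np.random.default_rng(7)
    x_small = rng.random(100)
    y_small = x_small + rng.normal(0, 0.05, 100)
    x_big = rng.random(1568)
    y_big = x_big + rng.normal(0, 0.05, 1568)
    for x, y in ((x_small, y_small), (x_big, y_big)):
        lo, hi = mc.ccc_confidence_interval(x, y)
        assert lo <= mc.ccc(x, y) <= hi
        assert -1.0 <= lo and hi <= 1.0
    w_small = np.diff(mc.ccc_confidence_interval(x_small, y_small))[0]
    w_big = np.diff(mc.ccc_confidence_interval(x_big, y_big))[0]
    assert w_big < w_small


def test_ci_degenerate_at_perfect_agreement():
    x = (0.1, 0.2, 0.3, 0.4)
    assert mc.ccc_confidence_interval(x, x) == (1.0, 1.0)


def test_ci_coverage_at_known_population_ccc():
    """95% interval covers the true CCC of a bivariate normal in ~95% of runs."""
    mu1, mu2, sd1, sd2, rho = 0.0, 0.2, 1.0, 1.2, 0.9
    true_ccc = 2 * rho * sd1 * sd2 / (sd1**2 + sd2**2 + (mu1 - mu2) ** 2)
    rng = np.random.default_rng(99)
    cov = [[sd1**2, rho * sd1 * sd2], [rho * sd1 * sd2, sd2**2]]
    hits = 0
    for _ in range(500):
        xy = rng.multivariate_normal([mu1, mu2], cov, size=200)
        lo, hi = mc.ccc_confidence_interval(xy[:, 0], xy[:, 1])
        hits += lo <= true_ccc <= hi
    assert 0.92 <= hits / 500 <= 0.98


@pytest.mark.parametrize(
    "y_fn, slope, intercept",
    [(lambda x: x, 1.0, 0.0), (lambda x: 0.5 * x + 0.1, 0.5, 0.1)],
)
def test_ols_line_exact_fits(y_fn, slope, intercept):
    x = np.array([0.1, 0.3, 0.5, 0.7, 0.9])
    s, i = mc.ols_line(x, y_fn(x))
    assert s == pytest.approx(slope, abs=1e-12)
    assert i == pytest.approx(intercept, abs=1e-12)


def test_ols_recovers_shrinkage_slope():
    rng = np.random.default_rng(3)
    x = rng.random(2000)
    y = x.mean() + 0.7 * (x - x.mean()) + rng.normal(0, 0.02, 2000)
    s, _ = mc.ols_line(x, y)
    assert s == pytest.approx(0.7, abs=0.03)


def test_ols_constant_regressor_rejected():
    with pytest.raises(ValueError, match="constant"):
        mc.ols_line((0.5, 0.5, 0.5), (0.1, 0.2, 0.3))


def _paired_from_vectors(x, y, concern="harm"):
    entries = [
        mc.scoring.PairedCell(mc.OpinionId(f"i{k}", mc.AFFIRMATIVE), concern, a, b, 10, 10)
        for k, (a, b) in enumerate(zip(x, y))
    ]
    return mc.PairedScores(entries=entries)


def test_variance_ratio_identity_and_scaling():
    x = np.array([0.1, 0.4, 0.7, 0.9])
    same = mc.variance_ratio(_paired_from_vectors(x, x))
    assert same["harm"].ratio == pytest.approx(1.0)
    shrunk = x.mean() + 0.5 * (x - x.mean())
    half = mc.variance_ratio(_paired_from_vectors(x, shrunk))
    assert half["harm"].ratio == pytest.approx(0.25)


def test_variance_ratio_flags_zero_denominator():
    out = mc.variance_ratio(_paired_from_vectors(np.full(4, 0.3), np.array([0.1, 0.2, 0.3, 0.4])))
    assert math.isnan(out["harm"].ratio)


def _table_from_scores(scores, concern="harm"):
    cells = {
        (mc.OpinionId(f"i{k}", mc.AFFIRMATIVE), concern): mc.CellCount(int(round(s * 100)), 100)
        for k, s in enumerate(scores)
    }
    return mc.ScoreTable(population_label="t", cells=cells)


def test_boxplot_whiskers_reach_extremes_without_outliers():
    table = _table_from_scores([0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9])
    box = mc.boxplot_summary(table).concerns["harm"]
    assert box.whisker_low == 0.1 and box.whisker_high == 0.9
    assert box.outliers == () and box.extreme_outliers == ()
    assert box.median == pytest.approx(0.5)


def test_boxplot_classifies_extreme_outlier():
    scores = [0.30, 0.31, 0.32, 0.33, 0.34, 0.35, 0.36, 0.37]
    # IQR ~0.035; a point 10 IQRs above Q3 is an extreme outlier
    scores.append(0.37 + 0.40)
    box = mc.boxplot_summary(_table_from_scores(scores)).concerns["harm"]
    assert box.extreme_outliers == (pytest.approx(0.77),)
    assert box.whisker_high < 0.5
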