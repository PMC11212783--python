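"""Measure formulas: worked examples, algebraic identities, degeneracy
handling, and agreement with brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import profilesim as ps
from profilesim.measures import evaluate_batch

from .conftest import make_context, make_random_pairs
from .oracles import concordance_counts, tau_star_enumeration


def ev(measure, x, y, ctx=None):
    return ps.evaluate_measure(measure, ps.ProfilePair(x, y), ctx)


def default_ctx(p, ranges=None, means=None, sds=None, midpoints=None, k=None):
    return ps.MeasureContext(
        variable_count=p,
        ranges=None if ranges is None else np.asarray(ranges, float),
        means=None if means is None else np.asarray(means, float),
        sds=None if sds is None else np.asarray(sds, float),
        midpoints=None if midpoints is None else np.asarray(midpoints, float),
        cattell_k=k)


# ---------------------------------------------------------------------------
# worked examples

@pytest.mark.parametrize("measure,x,y,expected", [
    ("euclidean", (1, 2, 3), (1, 2, 3), 0.0),
    ("euclidean", (0, 0), (3, 4), 5.0),
    ("manhattan", (1, 2), (2, 4), 3.0),
    ("chebyshev", (1, 2), (2, 4), 2.0),
    ("avg_l1_linf", (1, 2), (2, 4), 2.5),
    ("mean_character", (1, 2), (2, 4), 1.5),
    ("squared_euclidean", (1, 2), (2, 4), 5.0),
    ("lorentzian", (1, 2), (2, 4), math.log(2) + math.log(3)),
    ("penrose_size", (4, 0), (1, 1), 1.0),     # mean difference 1
    ("penrose_shape", (4, 0), (1, 1), 4.0),    # mean sq diff 5 - size 1
    ("cosine", (1, 2), (2, 4), 1.0),
    ("cosine", (1, 0), (0, 1), 0.0),
    ("angular_distance", (1, 0), (0, 1), 0.5),
    ("orloci", (1, 2), (2, 4), 0.0),
    ("icc_double_entry", (1, 2), (2, 1), -1.0),
    ("extended_dice", (1, 1), (1, 1), 1.0),
    ("ruzicka", (2, 3), (2, 3), 1.0),
    ("soergel", (2, 3), (2, 3), 0.0),
    ("motyka", (1, 2), (2, 2), 3.0 / 7.0),
    ("bray_curtis_sim", (1, 2), (2, 2), 6.0 / 7.0),
    ("bray_curtis_dist", (1, 2), (2, 2), 1.0 / 7.0),
    ("spearman_corr", (1, 2, 3), (3, 2, 1), -1.0),
    ("gamma", (1, 2, 3, 4), (1, 3, 2, 4), 2.0 / 3.0),   # C=5, D=1
    ("kendall_tau_b", (1, 2, 3, 4), (1, 3, 2, 4), 2.0 / 3.0),
    ("kendall_cov", (1, 2, 3, 4), (1, 3, 2, 4), 2.0 / 3.0),  # no ties
    ("inner_product", (1, 2), (3, 4), 11.0),
    ("pearson_corr", (1, 2, 3), (1, 2, 3), 1.0),
])
def test_worked_examples(measure, x, y, expected):
    assert ev(measure, x, y) == pytest.approx(expected, abs=1e-12)


def test_zero_variance_pearson_is_missing():
    assert ps.is_missing(ev("pearson_corr", (1, 1, 1), (1, 2, 3)))


def test_cosine_zero_norm_is_missing():
    assert ps.is_missing(ev("cosine", (0, 0), (1, 2)))


def test_gamma_all_tied_is_missing():
    assert ps.is_missing(ev("gamma", (2, 2, 2), (1, 2, 3)))


def test_mean_censored_euclidean():
    # m counts variables where not both scores are zero
    assert ev("mean_censored_euclidean", (0, 3, 0), (0, 0, 4)) == \
        pytest.approx(5.0 / math.sqrt(2))
    assert ps.is_missing(ev("mean_censored_euclidean", (0, 0), (0, 0)))


def test_canberra_strict_zero_zero_term_is_missing():
    assert ps.is_missing(ev("canberra", (0, 1), (0, 1)))
    # term-skipping policy is available as an option
    from profilesim.measures import _canberra
    v = _canberra(np.array([[0.0, 1.0]]), np.array([[0.0, 3.0]]), None,
                  policy="skip")
    assert v[0] == pytest.approx(0.5)


def test_range_scaled_variants():
    ctx = default_ctx(2, ranges=(2.0, 4.0))
    assert ev("gower", (1, 2), (2, 4), ctx) == pytest.approx(0.5)
    assert ev("scaled_euclidean", (1, 2), (2, 4), ctx) == \
        pytest.approx(math.sqrt(0.25 + 0.25))
    assert ev("half_range_standardized", (1, 2), (2, 4), ctx) == \
        pytest.approx(2 * math.sqrt(0.5))
    assert ev("max_scaled_difference", (1, 2), (2, 4), ctx) == \
        pytest.approx(0.5)


def test_burrows_delta_equals_mean_character_under_unit_sds():
    X, Y = make_random_pairs(50, 6, seed=11)
    ctx = default_ctx(6, means=np.zeros(6), sds=np.ones(6))
    delta = evaluate_batch("burrows_delta", X, Y, ctx)
    mc = evaluate_batch("mean_character", X, Y, None)
    np.testing.assert_allclose(delta, mc, atol=1e-12)


def test_cattell_rp_identity_and_bipolarity():
    ctx = default_ctx(4, k=3.0)
    assert ev("cattell_rp", (1, 2, 3, 4), (1, 2, 3, 4), ctx) == 1.0
    # large profile separation pushes toward (but never reaches) -1
    far = ev("cattell_rp", (0, 0, 0, 0), (50, 50, 50, 50), ctx)
    assert -1.0 < far < 0.0


def test_morisita_horn_identity():
    x = (1.0, 2.0, 5.0)
    assert ev("morisita_horn", x, x) == pytest.approx(1.0)


def test_morisita_centered_data_degrades_gracefully():
    # N_x(N_x - 1) = 0 is a data degeneracy, not an error
    assert ps.is_missing(ev("morisita", (0.5, 0.5), (1.0, 2.0)))


def test_dcor_affine_invariance_and_constant():
    x = np.array([1.0, 2.0, 5.0, 3.0, 0.0])
    assert ev("dcor", x, x) == pytest.approx(1.0)
    assert ev("dcor", x, 2 * x + 1) == pytest.approx(1.0)
    assert ev("dcor", x, -3 * x + 2) == pytest.approx(1.0)
    assert ev("dcov", np.full(5, 2.0), x) == pytest.approx(0.0)
    assert ev("dcor", np.full(5, 2.0), x) == pytest.approx(0.0)


def test_dcor_matches_independent_implementation():
    pingouin = pytest.importorskip("pingouin")
    rng = np.random.default_rng(5)
    for _ in range(5):
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        ours = ev("dcor", x, y)
        theirs = pingouin.distance_corr(x, y, n_boot=None)
        assert ours == pytest.approx(float(theirs), abs=1e-10)


def test_tau_star_matches_enumeration_oracle():
    rng = np.random.default_rng(7)
    for p in (4, 5, 6, 8):
        for _ in range(4):
            x = rng.normal(size=p)
            y = rng.normal(size=p)
            assert ev("tau_star", x, y) == \
                pytest.approx(tau_star_enumeration(x, y), abs=1e-12)
    # order-reversal via z -> 5 - z preserves all |z_i - z_j|
    assert ev("tau_star", (1, 2, 3, 4), (4, 3, 2, 1)) == \
        pytest.approx(ev("tau_star", (1, 2, 3, 4), (1, 2, 3, 4)))
    # frozen fixture from the enumeration oracle: comonotone profiles
    assert tau_star_enumeration((1, 2, 3, 4), (1, 2, 3, 4)) == \
        pytest.approx(2.0 / 3.0)
    assert ev("tau_star", (1, 2, 3, 4), (1, 2, 3, 4)) == \
        pytest.approx(2.0 / 3.0)


def test_tau_star_needs_four_variables():
    with pytest.raises(ValueError):
        ev("tau_star", (1, 2, 3), (1, 2, 3))


def test_rank_measures_match_pair_counting():
    rng = np.random.default_rng(13)
    for _ in range(10):
        x = rng.integers(0, 5, size=8).astype(float)
        y = rng.integers(0, 5, size=8).astype(float)
        C, D, Tx, Ty = concordance_counts(x, y)
        n0 = 8 * 7 / 2
        got_cov = ev("kendall_cov", x, y)
        assert got_cov == pytest.approx((C - D) / n0)
        if C + D > 0:
            assert ev("gamma", x, y) == pytest.approx((C - D) / (C + D))
        den = math.sqrt((n0 - Tx) * (n0 - Ty))
        if den > 0:
            assert ev("kendall_tau_b", x, y) == pytest.approx((C - D) / den)


def test_spearman_equals_rank_then_correlate():
    rng = np.random.default_rng(17)
    from scipy import stats
    for _ in range(10):
        x = rng.normal(size=7)
        y = rng.normal(size=7)
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        assert ev("spearman_corr", x, y) == \
            pytest.approx(np.corrcoef(rx, ry)[0, 1], abs=1e-12)
        assert ev("spearman_cov", x, y) == \
            pytest.approx(np.cov(rx, ry, ddof=1)[0, 1], abs=1e-12)


def test_monotone_invariance_of_rank_and_sign_measures():
    rng = np.random.default_rng(19)
    x = rng.normal(size=8)
    y = rng.normal(size=8)
    fx = np.exp(x)            # strictly increasing
    gy = y ** 3 + 2 * y       # strictly increasing
    for m in ("spearman_corr", "kendall_tau_b", "gamma", "tau_star"):
        assert ev(m, fx, gy) == pytest.approx(ev(m, x, y), abs=1e-12)


def test_cohen_rc_is_cosine_of_midpoint_centered_scores():
    ctx = default_ctx(2, midpoints=(4.0, 4.0))
    assert ev("cohen_rc", (5, 3), (5, 3), ctx) == pytest.approx(1.0)
    assert ev("cohen_rc", (5, 3), (3, 5), ctx) == pytest.approx(-1.0)


def test_mccrae_rewards_extremeness_and_is_symmetric():
    ctx = default_ctx(4, means=np.zeros(4), sds=np.ones(4))
    extreme = (2.0, -2.0, 2.0, -2.0)
    mild = (0.5, -0.5, 0.5, -0.5)
    for m in ("mccrae_coefficient", "mccrae_index"):
        assert ev(m, extreme, extreme, ctx) > ev(m, mild, mild, ctx)
    rng = np.random.default_rng(23)
    x = rng.normal(size=4)
    y = rng.normal(size=4)
    assert ev("mccrae_coefficient", x, y, ctx) == \
        pytest.approx(ev("mccrae_coefficient", y, x, ctx))


def test_mccrae_index_regression_value():
    # frozen from the transcribed formula: k=2, z-profiles (1,-1), (1,1):
    # M = (1, 0), D = (0, -2)  =>  I_pa = (2 + 2*1 - 4/2) / 2 = 1
    ctx = default_ctx(2, means=np.zeros(2), sds=np.ones(2))
    assert ev("mccrae_index", (1.0, -1.0), (1.0, 1.0), ctx) == \
        pytest.approx(1.0)


def test_errors_on_misuse():
    with pytest.raises(ValueError):
        ps.ProfilePair([1, 2], [1, 2, 3])
    with pytest.raises(ValueError):
        ps.ProfilePair([1], [2])
    with pytest.raises(KeyError):
        ev("not_a_measure", (1, 2), (1, 2))
    with pytest.raises(ValueError):
        ev("gower", (1, 2), (1, 2))  # missing required ranges


# ---------------------------------------------------------------------------
# algebraic identities on random pairs

def test_complement_and_duplicate_identities():
    X, Y = make_random_pairs(100, 6, seed=29, nonnegative=True)
    ruz = evaluate_batch("ruzicka", X, Y)
    soe = evaluate_batch("soergel", X, Y)
    np.testing.assert_allclose(soe, 1.0 - ruz, atol=1e-12)
    bcs = evaluate_batch("bray_curtis_sim", X, Y)
    bcd = evaluate_batch("bray_curtis_dist", X, Y)
    np.testing.assert_allclose(bcd, 1.0 - bcs, atol=1e-12)
    np.testing.assert_allclose(evaluate_batch("czekanowski_dist", X, Y),
                               bcd, atol=0)
    l1 = evaluate_batch("manhattan", X, Y)
    linf = evaluate_batch("chebyshev", X, Y)
    np.testing.assert_allclose(evaluate_batch("avg_l1_linf", X, Y),
                               (l1 + linf) / 2, atol=1e-12)
    np.testing.assert_allclose(evaluate_batch("mean_character", X, Y),
                               l1 / 6, atol=1e-12)
    cos = evaluate_batch("cosine", X, Y)
    np.testing.assert_allclose(evaluate_batch("orloci", X, Y),
                               np.sqrt(2 * (1 - cos)), atol=1e-9)
    np.testing.assert_allclose(evaluate_batch("angular_distance", X, Y),
                               np.arccos(cos) / math.pi, atol=1e-12)


def _symmetry_check(X, Y, ctx):
    for d in ps.CATALOG:
        fwd = evaluate_batch(d.id, X, Y, ctx)
        bwd = evaluate_batch(d.id, Y, X, ctx)
        both_nan = np.isnan(fwd) & np.isnan(bwd)
        np.testing.assert_allclose(np.where(both_nan, 0.0, fwd),
                                   np.where(both_nan, 0.0, bwd),
                                   atol=1e-12, err_msg=d.id)


def test_symmetry_all_measures():
    X, Y = make_random_pairs(50, 6, seed=31)
    _symmetry_check(X, Y, make_context(X, Y))
    Xp, Yp = make_random_pairs(50, 6, seed=37, nonnegative=True)
    _symmetry_check(Xp, Yp, make_context(Xp, Yp))


def test_identity_behavior_on_equal_profiles():
    rng = np.random.default_rng(41)
    X = rng.normal(size=(20, 6))
    ctx = make_context(X, X)
    for d in ps.CATALOG:
        if d.group == "G1_difference" and d.id != "cattell_rp":
            vals = evaluate_batch(d.id, X, X, ctx)
            np.testing.assert_allclose(vals, 0.0, atol=1e-12, err_msg=d.id)
    np.testing.assert_allclose(evaluate_batch("cattell_rp", X, X, ctx), 1.0)
    for m in ("cosine", "spearman_corr", "pearson_corr",
              "icc_double_entry", "dcor"):
        np.testing.assert_allclose(evaluate_batch(m, X, X, ctx), 1.0,
                                   atol=1e-9, err_msg=m)


# ---------------------------------------------------------------------------
# hypothesis property checks

@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.lists(st.integers(0, 6), min_size=4, max_size=8),
       st.lists(st.integers(0, 6), min_size=4, max_size=8))
def test_complement_identity_property(xs, ys):
    p = min(len(xs), len(ys))
    x = np.array(xs[:p], dtype=float)
    y = np.array(ys[:p], dtype=float)
    r = ev("ruzicka", x, y)
    s = ev("soergel", x, y)
    if np.isnan(r) or np.isnan(s):
        assert np.isnan(r) and np.isnan(s)
    else:
        assert r + s == pytest.approx(1.0, abs=1e-12)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.lists(st.floats(-5, 5, allow_nan=False), min_size=4, max_size=8),
       st.lists(st.floats(-5, 5, allow_nan=False), min_size=4, max_size=8))
def test_bounded_measures_stay_bounded_property(xs, ys):
    p = min(len(xs), len(ys))
    x = np.array(xs[:p], dtype=float)
    y = np.array(ys[:p], dtype=float)
    for m in ("pearson_corr", "spearman_corr", "kendall_tau_b", "gamma",
              "cosine", "icc_double_entry", "dcor"):
        v = ev(m, x, y)
        if not np.isnan(v):
            lo, hi = ps.get_definition(m).bounds
            assert lo - 1e-12 <= v <= hi + 1e-12
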