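"""Fractional ranks, concentration index and concentration curve."""

import numpy as np
import pytest
from helpers import make_dataset
from hypothesis import given, settings
from hypothesis import strategies as st

import healthequity as he


class TestFractionalRank:
    def test_equal_weight_closed_form(self):
        assert np.allclose(he.fractional_rank([5, 6, 7, 8]), [0.125, 0.375, 0.625, 0.875])

    def test_tied_block_shares_midpoint(self):
        ranks = he.fractional_rank([1.0, 1.0, 2.0, 3.0])
        assert np.allclose(ranks, [0.25, 0.25, 0.625, 0.875])

    def test_weights_shift_the_midpoints(self):
        # weight 2 on the poorest record doubles its mass: ranks (1, 2.5, 3.5)/4
        ranks = he.fractional_rank([1.0, 2.0, 3.0], weights=[2.0, 1.0, 1.0])
        assert np.allclose(ranks, [0.25, 0.625, 0.875])

    def test_ranks_nondecreasing_in_living_standard(self, rng):
        x = rng.normal(size=200)
        r = he.fractional_rank(x)
        order = np.argsort(x)
        assert np.all(np.diff(r[order]) >= 0)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(he.ValidationError):
            he.fractional_rank([1.0, 2.0], weights=[0.0, 0.0])


class TestConcentrationIndex:
    def test_constant_outcome_is_exact_zero(self):
        est = he.concentration_index(np.ones(100), np.arange(100.0))
        assert est.value == 0.0

    def test_two_record_hand_computation(self):
        # mu=0.5, midpoint ranks (0.25, 0.75), cov=0.125 -> C = 2*0.125/0.5
        est = he.concentration_index([0.0, 1.0], [1.0, 2.0])
        assert est.value == pytest.approx(0.5)

    def test_reversing_ranking_negates_index(self, rng):
        y = rng.integers(0, 2, 80).astype(float)
        y[0] = 1.0
        x = rng.normal(size=80)
        a = he.concentration_index(y, x).value
        b = he.concentration_index(y, -x).value
        assert a == pytest.approx(-b)

    def test_rank_shift_invariance(self, rng):
        y = rng.uniform(0.1, 1.0, 50)
        r = he.fractional_rank(rng.normal(size=50))
        a = he.concentration_index(y, rank=r).value
        b = he.concentration_index(y, rank=r + 0.123).value
        assert a == pytest.approx(b, rel=1e-9)

    def test_zero_mean_outcome_undefined(self):
        with pytest.raises(he.concentration.UndefinedIndexError):
            he.concentration_index(np.zeros(10), np.arange(10.0))

    def test_duplicating_record_equals_doubling_weight(self, rng):
        y = rng.integers(0, 2, 30).astype(float)
        y[:3] = 1.0
        x = rng.normal(size=30)
        dup = he.concentration_index(np.r_[y, y[0]], np.r_[x, x[0]]).value
        wtd = he.concentration_index(y, x, weights=np.r_[2.0, np.ones(29)]).value
        assert dup == pytest.approx(wtd, rel=1e-12)

    def test_binary_outcome_bound(self, rng):
        for _ in range(25):
            y = rng.integers(0, 2, 120).astype(float)
            if y.sum() == 0:
                continue
            est = he.concentration_index(y, rng.normal(size=120))
            assert abs(est.value) <= 1.0 - est.mu + 1e-12

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.integers(0, 10_000), st.floats(0.1, 50.0))
    def test_scale_invariance(self, seed, scale):
        rng = np.random.default_rng(seed)
        y = rng.uniform(0.0, 1.0, 40)
        x = rng.normal(size=40)
        a = he.concentration_index(y, x).value
        b = he.concentration_index(scale * y, x).value
        assert a == pytest.approx(b, rel=1e-9, abs=1e-12)

    def test_estimator_api_matches_function(self, rng):
        y = rng.integers(0, 2, 200).astype(float)
        y[0] = 1.0
        x = rng.normal(size=200)
        est = he.ConcentrationIndex().fit(x.reshape(-1, 1), y)
        ref = he.concentration_index(y, x)
        assert est.value_ == ref.value
        assert est.se_ == pytest.approx(ref.se)
        assert est.ci95_[0] <= est.value_ <= est.ci95_[1]
        params = est.get_params()
        assert params == {"compute_se": True}


class TestConcentrationCurve:
    def test_equal_outcome_lies_on_diagonal(self):
        curve = he.concentration_curve(np.ones(10), np.arange(10.0))
        assert np.allclose(curve.p, curve.L)

    def test_outcome_held_by_richest_only(self):
        curve = he.concentration_curve([0, 0, 0, 1], [1.0, 2.0, 3.0, 4.0])
        expected = np.array([[0, 0], [0.25, 0], [0.5, 0], [0.75, 0], [1, 1.0]])
        assert np.allclose(curve.points, expected)

    def test_zero_total_outcome_rejected(self):
        with pytest.raises(he.ValidationError):
            he.concentration_curve(np.zeros(5), np.arange(5.0))

    def test_coordinates_monotone(self, rng):
        y = rng.uniform(0, 1, 100)
        curve = he.concentration_curve(y, rng.normal(size=100), rng.uniform(0.5, 2.0, 100))
        assert np.all(np.diff(curve.p) >= 0) and np.all(np.diff(curve.L) >= 0)
        assert curve.points[0].tolist() == [0.0, 0.0]
        assert np.allclose(curve.points[-1], [1.0, 1.0])

    @pytest.mark.parametrize("seed", range(5))
    def test_area_route_matches_covariance_route(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 500))
        y = rng.uniform(0, 1, n)
        x = rng.normal(size=n)
        cov_ci = he.concentration_index(y, x).value
        area_ci = he.curve_area_index(he.concentration_curve(y, x))
        assert abs(cov_ci - area_ci) <= 2.0 / n


class TestCiByGroup:
    def test_single_group_equals_whole_sample(self, rng):
        y = rng.integers(0, 2, 100).astype(float)
        y[0] = 1.0
        x = rng.normal(size=100)
        ds = make_dataset(y, x, extra={"g": ["a"] * 100})
        table = he.ci_by_group(ds, "g")
        ref = he.concentration_index(y, x)
        assert len(table) == 1
        assert table.loc[0, "value"] == ref.value

    def test_opposite_gradients_have_opposite_signs(self):
        n = 200
        x = np.arange(float(n))
        pro_rich = (x >= 0.7 * n).astype(float)  # outcome held by the richest
        pro_poor = (x <= 0.3 * n).astype(float)  # outcome held by the poorest
        ds = make_dataset(
            np.r_[pro_rich, pro_poor],
            np.r_[x, x],
            extra={"g": ["rich_side"] * n + ["poor_side"] * n},
        )
        table = he.ci_by_group(ds, "g").set_index("g")
        assert table.loc["rich_side", "value"] > 0.5
        assert table.loc["poor_side", "value"] < -0.5

    def test_small_stratum_flagged(self, rng):
        y = np.r_[rng.integers(0, 2, 50).astype(float), [1.0, 0.0, 1.0]]
        x = rng.normal(size=53)
        ds = make_dataset(y, x, extra={"g": ["big"] * 50 + ["tiny"] * 3})
        with pytest.warns(UserWarning, match="tiny"):
            table = he.ci_by_group(ds, "g").set_index("g")
        assert bool(table.loc["tiny", "small_stratum"]) is True
        assert bool(table.loc["big", "small_stratum"]) is False
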