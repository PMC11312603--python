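"""Probit marginal effects, the decomposition identity, and horizontal inequity."""

import numpy as np
import pandas as pd
import pytest
from helpers import make_dataset
from scipy import stats

import healthequity as he
from healthequity.decomposition import FitError


def _random_binary_design(rng, n, names=("a", "b"), p=0.5):
    return pd.DataFrame({name: rng.integers(0, 2, n).astype(float) for name in names})


class TestProbitMarginalEffects:
    def test_null_model_effects_near_zero(self):
        rng = np.random.default_rng(7)
        n = 20_000
        X = _random_binary_design(rng, n, names=("a", "b", "c"))
        y = (rng.uniform(size=n) < 0.3).astype(float)
        est = he.ProbitMarginalEffects().fit(X, y)
        assert np.all(np.abs(est.ame_) < 0.05)

    def test_coefficient_recovery(self):
        rng = np.random.default_rng(42)
        n = 20_000
        x = rng.standard_normal(n)
        y = (rng.uniform(size=n) < stats.norm.cdf(-0.5 + 1.0 * x)).astype(float)
        est = he.ProbitMarginalEffects().fit(pd.DataFrame({"x": x}), y)
        assert est.params_["x"] == pytest.approx(1.0, abs=0.05)
        assert est.converged_

    def test_ame_matches_finite_difference(self):
        rng = np.random.default_rng(3)
        n = 5_000
        x = rng.standard_normal(n)
        z = rng.integers(0, 2, n).astype(float)
        y = (rng.uniform(size=n) < stats.norm.cdf(-0.3 + 0.8 * x + 0.4 * z)).astype(float)
        X = pd.DataFrame({"x": x, "z": z})
        est = he.ProbitMarginalEffects().fit(X, y)
        h = 1e-5
        up, down = X.copy(), X.copy()
        up["x"] += h
        down["x"] -= h
        fd = (est.predict(up).mean() - est.predict(down).mean()) / (2 * h)
        assert est.ame_["x"] == pytest.approx(fd, rel=1e-6)

    def test_single_class_outcome_rejected(self, rng):
        X = _random_binary_design(rng, 50)
        with pytest.raises(FitError):
            he.ProbitMarginalEffects().fit(X, np.ones(50))

    def test_rank_deficiency_names_columns(self, rng):
        X = _random_binary_design(rng, 100, names=("a",))
        X["copy_of_a"] = X["a"]
        y = rng.integers(0, 2, 100).astype(float)
        with pytest.raises(FitError, match="copy_of_a"):
            he.ProbitMarginalEffects().fit(X, y)


def _synthetic_single_driver(n=30_000, role="control", seed=9):
    """Outcome driven solely by one binary regressor correlated with income rank."""
    coef0 = {k: 0.0 for k in he.simulate.DEFAULT_PROBIT_COEFFICIENTS}
    var = "edu_junior_plus" if role == "control" else "chronic"
    cfg = he.SyntheticConfig(
        n_individuals=n,
        waves=(2011,),
        probit_coefficients={**coef0, var: 0.8},
        rank_gradient=0.0,
        correlation=((var, "expenditure", 0.7),),
        target_mean=0.3,
    )
    return he.generate_panel(cfg, seed=seed), var


class TestDecomposition:
    def test_zero_marginal_effects_force_residual(self, rng):
        y = rng.integers(0, 2, 400).astype(float)
        y[0] = 1.0
        x = rng.normal(size=400)
        ds = make_dataset(
            y, x,
            extra={"a": rng.integers(0, 2, 400).astype(float)},
            need=("a",),
        )
        res = he.decompose_ci(ds, marginal_effects={"a": 0.0})
        assert res.rows["contribution"].tolist() == [0.0]
        assert res.residual_contribution == res.total_ci.value
        assert res.hi == res.total_ci.value

    def test_single_driver_explains_total(self):
        ds, var = _synthetic_single_driver()
        res = he.decompose_ci(ds)
        total = res.total_ci.value
        row = res.rows.set_index("variable").loc[var]
        assert total > 0.05  # the built-in gradient is material
        assert row["contribution"] == pytest.approx(total, rel=0.15)
        assert abs(res.residual_contribution) < 0.15 * abs(total)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_additivity_and_percent_sum(self, seed):
        cfg = he.SyntheticConfig(n_individuals=2_000, waves=(2011,), target_mean=0.3)
        ds = he.generate_panel(cfg, seed=seed)
        res = he.decompose_ci(ds)
        total = res.total_ci.value
        assert res.rows["contribution"].sum() + res.residual_contribution == pytest.approx(
            total, abs=1e-15
        )
        assert res.rows["pct_contribution"].sum() + res.residual_pct == pytest.approx(
            100.0, abs=1e-8
        )

    def test_regressor_order_invariance(self):
        cfg = he.SyntheticConfig(n_individuals=2_000, waves=(2011,), target_mean=0.3)
        ds = he.generate_panel(cfg, seed=4)
        res1 = he.decompose_ci(ds)
        from dataclasses import replace

        shuffled = he.AnalyticDataset(
            ds.records,
            replace(ds.roles, need=ds.roles.need[::-1], control=ds.roles.control[::-1]),
            ds.dropped,
            ds.meta,
        )
        res2 = he.decompose_ci(shuffled)
        merged = res1.rows.set_index("variable").join(
            res2.rows.set_index("variable"), rsuffix="_r"
        )
        assert np.allclose(merged["contribution"], merged["contribution_r"])
        assert res1.hi == pytest.approx(res2.hi, rel=1e-12)

    def test_remainder_matches_generalized_residual_ci(self):
        cfg = he.SyntheticConfig(n_individuals=3_000, waves=(2011,), target_mean=0.3)
        ds = he.generate_panel(cfg, seed=6)
        res = he.decompose_ci(ds)
        fit = he.fit_probit(ds)
        direct = he.residual_generalized_ci(
            ds.records, ds.outcome, fit.ame, living_standard=ds.roles.living_standard
        )
        assert res.residual_contribution == pytest.approx(direct, abs=1e-10)

    def test_tiny_total_ci_suppresses_percentages(self):
        # y symmetric in the ranking: cov(y, r) is exactly zero
        y = np.array([1.0, 0.0, 0.0, 1.0] * 25)
        x = np.arange(100.0)
        ds = make_dataset(y, x, extra={"a": np.tile([0.0, 1.0], 50)}, need=("a",))
        with pytest.warns(UserWarning, match="percent"):
            res = he.decompose_ci(ds, marginal_effects={"a": 0.1})
        assert np.isnan(res.residual_pct)
        assert res.rows["pct_contribution"].isna().all()


class TestHorizontalInequity:
    @staticmethod
    def _result(total, contribs, need):
        rows = pd.DataFrame(
            {
                "variable": list(contribs),
                "role": ["need" if v in need else "control" for v in contribs],
                "contribution": list(contribs.values()),
            }
        )
        est = he.CIEstimate(value=total, se=np.nan, ci95=(np.nan, np.nan), mu=0.3, n=100)
        return he.DecompositionResult(
            rows=rows,
            residual_contribution=total - rows["contribution"].sum(),
            residual_pct=np.nan,
            total_ci=est,
            hi=total - rows.loc[rows["role"] == "need", "contribution"].sum(),
            need=tuple(need),
        )

    def test_printed_value_arithmetic(self):
        # total 0.0080 with need contributions summing to -0.0050 gives HI 0.0130
        res = self._result(0.0080, {"age": -0.0030, "chronic": -0.0020, "edu": 0.0043}, ("age", "chronic"))
        assert he.horizontal_inequity(res) == pytest.approx(0.0130)

    def test_zero_need_contributions_leave_ci(self):
        res = self._result(0.02, {"age": 0.0, "edu": 0.015}, ("age",))
        assert he.horizontal_inequity(res) == pytest.approx(0.02)

    def test_unknown_variable_rejected(self):
        res = self._result(0.02, {"age": 0.0}, ("age",))
        with pytest.raises(he.ValidationError, match="nope"):
            he.horizontal_inequity(res, need_vars=("nope",))

    @pytest.mark.parametrize(
        "urban,rural,expected", [(0.0077, -0.0010, 0.0087), (0.0900, 0.0002, 0.0898)]
    )
    def test_hi_gap_pairs(self, urban, rural, expected):
        assert he.hi_gap(urban, rural) == pytest.approx(expected, abs=1e-12)

    def test_hi_gap_of_identical_values_is_zero(self):
        assert he.hi_gap(0.1234, 0.1234) == 0.0

    def test_hi_gap_requires_finite_inputs(self):
        with pytest.raises(he.ValidationError):
            he.hi_gap(np.nan, 0.0)
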