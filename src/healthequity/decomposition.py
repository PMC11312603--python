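"""Wagstaff decomposition of the concentration index and horizontal inequity.

For a binary utilization outcome, a probit model

.. math:: y = \\alpha^m + \\sum_j \\beta_j^m x_j + \\sum_k \\gamma_k^m z_k + \\varepsilon

is linearized with average marginal effects (:math:`\\beta_j^m`,
:math:`\\gamma_k^m`), where :math:`x_j` are need variables and :math:`z_k`
controls.  The concentration index then decomposes as

.. math:: C = \\sum_j \\frac{\\beta_j^m \\bar x_j}{\\mu} C_j
             + \\sum_k \\frac{\\gamma_k^m \\bar z_k}{\\mu} C_k
             + \\frac{GC_\\varepsilon}{\\mu}

with :math:`C_j` the concentration index of regressor :math:`x_j` against
the same fractional ranks and :math:`GC_\\varepsilon` the generalized
concentration index of the residual.  The horizontal inequity index removes
the need contributions:  HI = C − Σ (need contributions); positive HI means
that, at equal need, the better-off use more services.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

from .concentration import (
    CIEstimate,
    concentration_index,
    fractional_rank,
    weighted_cov,
    weighted_mean,
)
from .datasets import AnalyticDataset, ValidationError

_TINY_CI = 1e-6  # |total CI| below this suppresses percent contributions


class FitError(RuntimeError):
    """Model estimation failed (separation, non-convergence, rank deficiency)."""


def _check_design(X: pd.DataFrame) -> None:
    arr = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        consts = [c for c in X.columns if X[c].nunique() <= 1]
        dups = []
        cols = X.columns.tolist()
        for i, a in enumerate(cols):
            for b in cols[i + 1 :]:
                if np.allclose(X[a].to_numpy(float), X[b].to_numpy(float)):
                    dups.append((a, b))
        raise FitError(
            "design matrix is rank deficient "
            f"(rank {rank} < {arr.shape[1]}); constant columns: {consts}; "
            f"duplicated columns: {dups}"
        )


class ProbitMarginalEffects(BaseEstimator):
    """Probit fit with derivative-based average marginal effects.

    The AME of regressor *j* is the sample (weight-) average of
    ``phi(x'b) * b_j`` — the derivative of the predicted probability with
    respect to the regressor, averaged over records.  The same derivative
    form is used for dummy regressors, which is what makes the downstream
    decomposition a linear approximation.

    Attributes
    ----------
    params_ : pandas.Series
        ML coefficients (``const`` first).
    ame_ : pandas.Series
        Average marginal effect per regressor (no intercept entry).
    converged_ : bool
    llf_ : float
        Log-likelihood at the optimum.
    """

    def fit(self, X: pd.DataFrame, y, sample_weight=None):
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=float)
        classes = set(np.unique(y))
        if not classes <= {0.0, 1.0}:
            raise ValidationError(f"outcome must be binary 0/1, found {sorted(classes)}")
        if classes != {0.0, 1.0}:
            raise FitError("outcome has a single class; probit not identified")
        w = np.ones_like(y) if sample_weight is None else np.asarray(sample_weight, float)
        _check_design(X)
        design = sm.add_constant(X.astype(float), has_constant="add")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = sm.GLM(
                    y, design,
                    family=sm.families.Binomial(link=sm.families.links.Probit()),
                    freq_weights=w,
                )
                res = model.fit(maxiter=200)
        except Exception as exc:  # pragma: no cover - statsmodels failure path
            raise FitError(f"probit estimation failed: {exc}") from exc
        converged = bool(getattr(res, "converged", True))
        params = res.params
        if not converged or not np.all(np.isfinite(params)) or np.max(np.abs(params)) > 1e2:
            raise FitError(
                "probit did not converge cleanly (possible separation); "
                f"converged={converged}, max|coef|={np.max(np.abs(params)):.3g}"
            )
        xb = design.to_numpy(dtype=float) @ params.to_numpy()
        phi_bar = weighted_mean(stats.norm.pdf(xb), w)
        self.params_ = params
        self.ame_ = params.drop("const") * phi_bar
        self.converged_ = converged
        self.llf_ = float(res.llf)
        self.n_ = len(y)
        self._columns = list(X.columns)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        design = sm.add_constant(pd.DataFrame(X)[self._columns].astype(float), has_constant="add")
        return stats.norm.cdf(design.to_numpy(dtype=float) @ self.params_.to_numpy())


@dataclass(frozen=True)
class ProbitFit:
    """Plain-record view of a fitted probit (coefficients + marginal effects)."""

    params: pd.Series
    ame: pd.Series
    converged: bool
    llf: float
    n: int


def fit_probit(dataset: AnalyticDataset) -> ProbitFit:
    """Fit the utilization probit on the dataset's need + control regressors."""
    est = ProbitMarginalEffects().fit(
        dataset.records[list(dataset.roles.regressors)],
        dataset.outcome,
        sample_weight=dataset.weights,
    )
    return ProbitFit(est.params_, est.ame_, est.converged_, est.llf_, est.n_)


@dataclass
class DecompositionResult:
    """Per-variable contributions to the concentration index plus residual and HI."""

    rows: pd.DataFrame
    residual_contribution: float
    residual_pct: float
    total_ci: CIEstimate
    hi: float
    need: tuple[str, ...]

    @property
    def need_contribution(self) -> float:
        return float(self.rows.loc[self.rows["role"] == "need", "contribution"].sum())


class WagstaffDecomposition(BaseEstimator):
    """Decompose the concentration index into per-regressor contributions.

    Parameters
    ----------
    living_standard : str
        Column of ``X`` holding the ranking variable.
    need : tuple of str
        Need regressors (their contribution is legitimate inequality).
    control : tuple of str
        Control regressors.

    Attributes
    ----------
    rows_ : pandas.DataFrame
        One row per regressor: marginal effect, mean, elasticity, variable
        concentration index, absolute and percent contribution.
    residual_contribution_ : float
        ``GC_eps / mu``, computed as the exact remainder ``total - sum(rows)``.
    total_ci_ : CIEstimate
    hi_ : float
        Horizontal inequity index ``total - sum(need contributions)``.
    probit_ : ProbitMarginalEffects
    """

    def __init__(
        self,
        living_standard: str,
        need: tuple[str, ...] = (),
        control: tuple[str, ...] = (),
    ):
        self.living_standard = living_standard
        self.need = tuple(need)
        self.control = tuple(control)

    def fit(self, X: pd.DataFrame, y, sample_weight=None, *, marginal_effects=None):
        X = pd.DataFrame(X)
        y = np.asarray(y, dtype=float)
        w = np.ones_like(y) if sample_weight is None else np.asarray(sample_weight, float)
        regressors = list(self.need) + list(self.control)
        missing = [c for c in [self.living_standard, *regressors] if c not in X.columns]
        if missing:
            raise ValidationError(f"X lacks column(s): {missing}")

        rank = fractional_rank(X[self.living_standard].to_numpy(dtype=float), w)
        total = concentration_index(y, rank=rank, weights=w)
        mu = total.mu

        if marginal_effects is None:
            probit = ProbitMarginalEffects().fit(X[regressors], y, sample_weight=w)
            ame = probit.ame_
        else:
            probit = None
            ame = pd.Series(marginal_effects).reindex(regressors)
            if ame.isna().any():
                raise ValidationError(
                    f"marginal_effects lacks regressors: {ame.index[ame.isna()].tolist()}"
                )

        rows = []
        for var in regressors:
            x = X[var].to_numpy(dtype=float)
            effect = float(ame[var])
            xbar = weighted_mean(x, w)
            cov_xr = weighted_cov(x, rank, w)
            # contribution = elasticity * C_x = effect * 2*cov(x, r) / mu;
            # the x-mean cancels, so the contribution survives xbar == 0.
            contribution = 2.0 * effect * cov_xr / mu
            if abs(xbar) > 0:
                var_ci = 2.0 * cov_xr / xbar
                elasticity = effect * xbar / mu
            else:
                var_ci = float("nan")
                elasticity = float("nan")
            rows.append(
                dict(
                    variable=var,
                    role="need" if var in self.need else "control",
                    marginal_effect=effect,
                    mean=xbar,
                    elasticity=elasticity,
                    variable_ci=var_ci,
                    contribution=contribution,
                )
            )
        rows = pd.DataFrame(rows)
        explained = float(rows["contribution"].sum())
        residual = total.value - explained

        if abs(total.value) < _TINY_CI:
            warnings.warn(
                "total concentration index is ~0; percent contributions suppressed",
                stacklevel=2,
            )
            rows["pct_contribution"] = float("nan")
            residual_pct = float("nan")
        else:
            rows["pct_contribution"] = rows["contribution"] / total.value * 100.0
            residual_pct = residual / total.value * 100.0

        need_contrib = float(rows.loc[rows["role"] == "need", "contribution"].sum())
        self.rows_ = rows
        self.residual_contribution_ = residual
        self.residual_pct_ = residual_pct
        self.total_ci_ = total
        self.hi_ = total.value - need_contrib
        self.probit_ = probit
        self.rank_ = rank
        self.n_ = len(y)
        return self

    def to_result(self) -> DecompositionResult:
        return DecompositionResult(
            rows=self.rows_.copy(),
            residual_contribution=self.residual_contribution_,
            residual_pct=self.residual_pct_,
            total_ci=self.total_ci_,
            hi=self.hi_,
            need=tuple(self.need),
        )


def decompose_ci(dataset: AnalyticDataset, *, marginal_effects=None) -> DecompositionResult:
    """Wagstaff decomposition of a dataset's concentration index.

    ``marginal_effects`` (mapping regressor -> effect) bypasses the probit
    fit, e.g. to study the decomposition identity under imposed effects.
    """
    est = WagstaffDecomposition(
        living_standard=dataset.roles.living_standard,
        need=dataset.roles.need,
        control=dataset.roles.control,
    )
    est.fit(
        dataset.records,
        dataset.outcome,
        sample_weight=dataset.weights,
        marginal_effects=marginal_effects,
    )
    return est.to_result()


def horizontal_inequity(result: DecompositionResult, need_vars=None) -> float:
    """HI = total CI minus the summed contributions of the need variables."""
    rows = result.rows.set_index("variable")
    if need_vars is None:
        need_vars = result.need
    unknown = [v for v in need_vars if v not in rows.index]
    if unknown:
        raise ValidationError(f"unknown decomposition variable(s): {unknown}")
    return float(result.total_ci.value - rows.loc[list(need_vars), "contribution"].sum())


def hi_gap(hi_urban: float, hi_rural: float) -> float:
    """Urban-minus-rural difference in the horizontal inequity index."""
    if not (np.isfinite(hi_urban) and np.isfinite(hi_rural)):
        raise ValidationError("HI values must be finite")
    return float(hi_urban) - float(hi_rural)


def residual_generalized_ci(X, y, marginal_effects, living_standard, sample_weight=None) -> float:
    """Cross-check: ``GC_eps / mu`` computed directly from the residuals.

    eps = y - sum_j beta_j^m x_j (the intercept drops out of the covariance);
    the result equals the remainder-based residual contribution up to
    floating-point error.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    w = np.ones_like(y) if sample_weight is None else np.asarray(sample_weight, float)
    rank = fractional_rank(X[living_standard].to_numpy(dtype=float), w)
    mu = weighted_mean(y, w)
    eps = y.copy()
    for var, effect in dict(marginal_effects).items():
        eps = eps - float(effect) * X[var].to_numpy(dtype=float)
    return 2.0 * weighted_cov(eps, rank, w) / mu
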