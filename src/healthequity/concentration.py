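"""Fractional ranks, concentration curves and the concentration index.

The concentration index of an outcome :math:`Y` with respect to a
living-standard ranking is

.. math:: C = \\frac{2}{\\mu}\\,\\mathrm{cov}(Y_i, R_i)

where :math:`R_i` is the fractional rank of individual :math:`i` in the
living-standard distribution (poorest first) and :math:`\\mu` the outcome
mean.  ``C`` equals twice the area between the concentration curve and the
line of equality; positive values indicate pro-rich concentration.

Ranks here are weighted midpoint ranks: with equal weights and no ties they
equal :math:`(i - 1/2)/N`, a constant shift of the literal :math:`i/N`
convention, and the covariance in ``C`` is shift-invariant, so the estimate
is identical while ties and weights are handled coherently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from .datasets import AnalyticDataset, ValidationError


class UndefinedIndexError(ValueError):
    """The concentration index is undefined (outcome mean is zero)."""


def fractional_rank(living_standard, weights=None) -> np.ndarray:
    """Weighted midpoint fractional rank in (0, 1), poorest first.

    After sorting ascending, record *i* gets
    ``(sum of weights before i + w_i / 2) / total weight``; a block of
    records tied on the living standard shares the midpoint rank of the
    whole block.
    """
    x = np.asarray(living_standard, dtype=float)
    if weights is None:
        w = np.ones_like(x)
    else:
        w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValidationError("weights must be nonnegative")
    total = w.sum()
    if not total > 0:
        raise ValidationError("weights sum to zero; ranks undefined")

    order = np.argsort(x, kind="stable")
    xs, ws = x[order], w[order]
    new_block = np.r_[True, xs[1:] != xs[:-1]]
    block_id = np.cumsum(new_block) - 1
    block_w = np.bincount(block_id, weights=ws)
    block_end = np.cumsum(block_w)
    block_rank = (block_end - block_w / 2.0) / total
    ranks = np.empty_like(x)
    ranks[order] = block_rank[block_id]
    return ranks


def weighted_mean(a, w) -> float:
    a = np.asarray(a, dtype=float)
    w = np.asarray(w, dtype=float)
    return float(np.sum(w * a) / np.sum(w))


def weighted_cov(a, b, w) -> float:
    """Weighted *population* covariance (divide by total weight)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    w = np.asarray(w, dtype=float)
    total = w.sum()
    am = np.sum(w * a) / total
    bm = np.sum(w * b) / total
    return float(np.sum(w * (a - am) * (b - bm)) / total)


@dataclass(frozen=True)
class CIEstimate:
    """Concentration-index estimate with delta-method standard error."""

    value: float
    se: float
    ci95: tuple[float, float]
    mu: float
    n: int

    def __post_init__(self):
        lo, hi = self.ci95
        if np.isfinite(self.se):
            assert lo <= self.value <= hi


@dataclass(frozen=True)
class ConcentrationCurve:
    """Ordered (cumulative population share, cumulative outcome share) points."""

    points: np.ndarray  # shape (m, 2), starts (0,0), ends (1,1)

    @property
    def p(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def L(self) -> np.ndarray:
        return self.points[:, 1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points, columns=["population_share", "outcome_share"])


def _ci_standard_error(y, r, w, mu) -> float:
    # "Convenient regression": the WLS slope of 2*var_w(r)*(y/mu) on r equals
    # the covariance-formula index; its robust (HC1) standard error is the
    # delta-method SE.
    var_r = weighted_cov(r, r, w)
    if var_r <= 0 or len(y) < 3:
        return float("nan")
    lhs = 2.0 * var_r * (np.asarray(y, dtype=float) / mu)
    X = sm.add_constant(np.asarray(r, dtype=float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.WLS(lhs, X, weights=np.asarray(w, dtype=float)).fit(cov_type="HC1")
    return float(res.bse[1])


def concentration_index(
    outcome,
    living_standard=None,
    weights=None,
    *,
    rank=None,
    compute_se: bool = True,
) -> CIEstimate:
    """Concentration index ``C = (2/mu) * cov_w(Y, R)`` with 95% interval.

    Exactly one of ``living_standard`` (ranks computed here) or ``rank``
    (precomputed fractional ranks) must be supplied.  ``C = 0`` means
    perfect equality; ``C > 0`` means utilization concentrated among the
    better-off.
    """
    y = np.asarray(outcome, dtype=float)
    if weights is None:
        w = np.ones_like(y)
    else:
        w = np.asarray(weights, dtype=float)
    if rank is None:
        if living_standard is None:
            raise ValueError("supply either living_standard or rank")
        r = fractional_rank(living_standard, w)
    else:
        r = np.asarray(rank, dtype=float)

    mu = weighted_mean(y, w)
    if mu == 0:
        raise UndefinedIndexError("outcome mean is zero; concentration index undefined")
    value = 2.0 * weighted_cov(y, r, w) / mu
    se = _ci_standard_error(y, r, w, mu) if compute_se else float("nan")
    half = 1.96 * se if np.isfinite(se) else float("nan")
    ci95 = (value - half, value + half) if np.isfinite(se) else (float("nan"), float("nan"))
    return CIEstimate(value=value, se=se, ci95=ci95, mu=mu, n=len(y))


def concentration_curve(outcome, living_standard, weights=None) -> ConcentrationCurve:
    """Cumulative outcome share against cumulative population share.

    The population is sorted by living standard ascending; one point per
    record plus the origin.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(living_standard, dtype=float)
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    total_y = float(np.sum(w * y))
    if not total_y > 0:
        raise ValidationError("total outcome is zero; concentration curve undefined")
    order = np.argsort(x, kind="stable")
    cw = np.cumsum(w[order]) / w.sum()
    cy = np.cumsum((w * y)[order]) / total_y
    pts = np.column_stack([np.r_[0.0, cw], np.r_[0.0, cy]])
    return ConcentrationCurve(points=pts)


def curve_area_index(curve: ConcentrationCurve) -> float:
    """Twice the signed trapezoid area between the equality diagonal and the curve.

    A numeric-integration route to the index, used as an independent
    cross-check of the covariance formula.
    """
    return float(2.0 * np.trapezoid(curve.p - curve.L, curve.p))


class ConcentrationIndex(BaseEstimator):
    """Estimator wrapper: fit on (living standard, outcome) pairs.

    Parameters
    ----------
    compute_se : bool, default True
        Whether to compute the robust delta-method standard error.

    Attributes
    ----------
    value_ : float
        The concentration index.
    se_ : float
        Delta-method standard error (convenient regression, HC1).
    ci95_ : tuple of float
        ``value_ -/+ 1.96 * se_``.
    mu_ : float
        Weighted outcome mean.
    rank_ : ndarray
        Weighted midpoint fractional ranks.
    n_ : int
        Number of records.
    """

    def __init__(self, compute_se: bool = True):
        self.compute_se = compute_se

    def fit(self, X, y, sample_weight=None):
        x = np.asarray(X, dtype=float)
        if x.ndim == 2:
            if x.shape[1] != 1:
                raise ValueError("X must be a single living-standard column")
            x = x[:, 0]
        y = np.asarray(y, dtype=float)
        if x.shape[0] != y.shape[0]:
            raise ValueError("X and y lengths differ")
        w = np.ones_like(y) if sample_weight is None else np.asarray(sample_weight, float)
        self.rank_ = fractional_rank(x, w)
        est = concentration_index(y, rank=self.rank_, weights=w, compute_se=self.compute_se)
        self.estimate_ = est
        self.value_ = est.value
        self.se_ = est.se
        self.ci95_ = est.ci95
        self.mu_ = est.mu
        self.n_ = est.n
        self._x, self._y, self._w = x, y, w
        return self

    def curve(self) -> ConcentrationCurve:
        if not hasattr(self, "value_"):
            raise RuntimeError("fit the estimator before requesting the curve")
        return concentration_curve(self._y, self._x, self._w)


def ci_by_group(
    dataset: AnalyticDataset,
    group: str | None = None,
    min_n: int = 30,
) -> pd.DataFrame:
    """Concentration index per wave and group, ranks recomputed within stratum.

    Strata smaller than ``min_n`` are flagged (``small_stratum`` column) with
    a warning; empty strata simply do not appear.
    """
    df = dataset.records
    keys: list[str] = []
    if dataset.roles.wave is not None:
        keys.append(dataset.roles.wave)
    if group is not None:
        keys.append(group)
    rows = []
    groups = df.groupby(keys).indices.items() if keys else [(("all",), np.arange(len(df)))]
    for key, idx in groups:
        key = key if isinstance(key, tuple) else (key,)
        mask = np.zeros(len(df), dtype=bool)
        mask[idx] = True
        sub = dataset.subset(mask)
        small = sub.n < min_n
        if small:
            warnings.warn(f"stratum {key} has n={sub.n} < {min_n}; estimate flagged", stacklevel=2)
        est = concentration_index(sub.outcome, sub.living_standard, sub.weights)
        row = dict(zip(keys, key)) if keys else {"stratum": "all"}
        row.update(
            value=est.value, se=est.se, lower=est.ci95[0], upper=est.ci95[1],
            mu=est.mu, n=est.n, small_stratum=small,
        )
        rows.append(row)
    return pd.DataFrame(rows)
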