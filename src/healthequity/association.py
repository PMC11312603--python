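"""Stratified logistic regression with survey-year fixed effects (OR tables).

A pooled cross-section logit per residence stratum, with year dummies (and
any already-dummied region columns among the regressors) capturing the two
"fixed-effect" dimensions.  Coefficients are reported as odds ratios with
Wald 95% intervals; reference categories carry OR = 1.00.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from .datasets import AnalyticDataset, ValidationError
from .decomposition import FitError, _check_design


class FixedEffectsLogit(BaseEstimator):
    """Logit of a binary outcome on regressors plus categorical fixed effects.

    Parameters
    ----------
    fixed_effects : tuple of str
        Columns dummy-coded with their first (sorted) level as reference.

    Attributes
    ----------
    params_ : pandas.Series
        Log-odds coefficients.
    or_table_ : pandas.DataFrame
        variable, OR, lower, upper, p, is_reference rows.
    """

    def __init__(self, fixed_effects: tuple[str, ...] = ()):
        self.fixed_effects = tuple(fixed_effects)

    def fit(self, X: pd.DataFrame, y, sample_weight=None):
        X = pd.DataFrame(X).copy()
        y = np.asarray(y, dtype=float)
        if set(np.unique(y)) != {0.0, 1.0}:
            raise ValidationError("outcome must be binary with both classes present")
        w = np.ones_like(y) if sample_weight is None else np.asarray(sample_weight, float)

        design_parts = []
        references: list[str] = []
        for fe in self.fixed_effects:
            if fe not in X.columns:
                raise ValidationError(f"fixed-effect column {fe!r} not in X")
            levels = sorted(X[fe].unique().tolist())
            references.append(f"{fe}={levels[0]}")
            dummies = pd.get_dummies(X[fe], prefix=fe, prefix_sep="=").astype(float)
            design_parts.append(dummies.iloc[:, 1:])
            X = X.drop(columns=[fe])
        design_parts.append(X.astype(float))
        design = pd.concat(design_parts, axis=1)
        _check_design(design)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM(
                    y, sm.add_constant(design, has_constant="add"),
                    family=sm.families.Binomial(),
                    freq_weights=w,
                ).fit(maxiter=200)
        except Exception as exc:  # pragma: no cover
            raise FitError(f"logit estimation failed: {exc}") from exc
        params = res.params
        if not bool(getattr(res, "converged", True)) or np.max(np.abs(params)) > 1e2:
            raise FitError(
                "logit did not converge cleanly (possible separation); "
                f"max|coef|={np.max(np.abs(params)):.3g}"
            )
        conf = res.conf_int()
        pvals = res.pvalues

        rows = []
        for ref in references:
            rows.append(dict(variable=ref, OR=1.0, lower=np.nan, upper=np.nan,
                             p=np.nan, is_reference=True))
        with np.errstate(over="ignore"):  # sparse cells give huge Wald bounds
            for name in design.columns:
                rows.append(
                    dict(
                        variable=name,
                        OR=float(np.exp(params[name])),
                        lower=float(np.exp(conf.loc[name, 0])),
                        upper=float(np.exp(conf.loc[name, 1])),
                        p=float(pvals[name]),
                        is_reference=False,
                    )
                )
        self.params_ = params
        self.llf_ = float(res.llf)
        self.or_table_ = pd.DataFrame(rows)
        self.n_ = len(y)
        self._design_columns = list(design.columns)
        return self


def fit_fe_logit(
    dataset: AnalyticDataset,
    stratum: str | None = None,
    fixed_effects: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Table of odds ratios per stratum, with year fixed effects.

    ``fixed_effects`` defaults to the dataset's wave column.  Returns the
    concatenated OR tables with a ``stratum`` column.
    """
    if fixed_effects is None:
        fixed_effects = (dataset.roles.wave,) if dataset.roles.wave is not None else ()
    regressors = [c for c in dataset.roles.regressors if c != stratum]
    tables = []
    if stratum is None:
        strata = [("all", np.ones(dataset.n, dtype=bool))]
    else:
        strata = [
            (lev, (dataset.records[stratum] == lev).to_numpy())
            for lev in sorted(dataset.records[stratum].unique().tolist())
        ]
    for label, mask in strata:
        sub = dataset.subset(mask)
        keep = [c for c in regressors if sub.records[c].nunique() > 1]
        dropped = sorted(set(regressors) - set(keep))
        if dropped:
            warnings.warn(
                f"stratum {label!r}: dropping constant regressor(s) {dropped}", stacklevel=2
            )
        est = FixedEffectsLogit(fixed_effects=fixed_effects).fit(
            sub.records[list(fixed_effects) + keep],
            sub.outcome,
            sample_weight=sub.weights,
        )
        tab = est.or_table_.copy()
        tab.insert(0, "stratum", label)
        tables.append(tab)
    return pd.concat(tables, ignore_index=True)
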