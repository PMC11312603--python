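"""Descriptive tables, utilization rates and the end-to-end pipeline.

Emits the standard report bundle of an equity analysis: utilization rates by
wave and stratum, a descriptive table with group tests, OR tables from the
year-fixed-effect logit, per-wave/stratum concentration and horizontal
inequity indices, full decompositions, concentration-curve data and plots,
and a JSON manifest.  Percentages are printed to 2 decimals and indices to
4 decimals; full precision is kept in the JSON/CSV artifacts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .association import fit_fe_logit
from .concentration import concentration_curve, concentration_index
from .datasets import (
    AnalyticDataset,
    ConfigurationError,
    VariableRoleMap,
    add_tertile_dummies,
    assign_tertiles,
    load_dataset,
)
from .decomposition import decompose_ci
from .simulate import SyntheticConfig, generate_panel

logger = logging.getLogger(__name__)


def utilization_rates(dataset: AnalyticDataset, by: list[str] | None = None) -> pd.DataFrame:
    """Weighted percentage of outcome = 1 per cell, with cell n.

    ``by`` defaults to the wave column; empty cells simply do not appear.
    """
    if by is None:
        by = [dataset.roles.wave] if dataset.roles.wave is not None else []
    df = dataset.records.copy()
    df["_w"] = dataset.weights
    df["_wy"] = dataset.weights * dataset.outcome
    if not by:
        return pd.DataFrame(
            [{"rate_pct": 100.0 * df["_wy"].sum() / df["_w"].sum(), "n": len(df)}]
        )
    grouped = df.groupby(by, observed=True)
    out = grouped.agg(_w=("_w", "sum"), _wy=("_wy", "sum"), n=("_w", "size")).reset_index()
    out["rate_pct"] = 100.0 * out["_wy"] / out["_w"]
    return out.drop(columns=["_w", "_wy"])


def _is_categorical(s: pd.Series) -> bool:
    return (
        isinstance(s.dtype, pd.CategoricalDtype)
        or s.dtype == object
        or s.nunique(dropna=True) <= 10
    )


def describe_sample(
    dataset: AnalyticDataset, group: str, variables: list[str] | None = None
) -> pd.DataFrame:
    """Descriptive table by group: % for categorical rows (chi-square p),
    mean (SD) for continuous rows (Welch t / one-way ANOVA p)."""
    df = dataset.records
    if df[group].nunique() < 2:
        raise ConfigurationError(f"group column {group!r} has fewer than 2 levels")
    if variables is None:
        variables = [c for c in dataset.roles.regressors if c != group]
        variables.append(dataset.roles.living_standard)
    levels = sorted(df[group].unique().tolist())
    rows = []
    for var in variables:
        s = df[var]
        if _is_categorical(s):
            tab = pd.crosstab(s, df[group])
            if tab.shape[0] < 2:
                rows.append({"variable": var, "type": "categorical", "p": np.nan,
                             "note": "constant column; test skipped"})
                continue
            chi2, p, _, _ = stats.chi2_contingency(tab.to_numpy())
            for val, counts in tab.iterrows():
                row = {"variable": var, "level": val, "type": "categorical",
                       "statistic": chi2, "p": p}
                total = counts.sum()
                row["total"] = f"{total} ({100.0 * total / len(df):.2f})"
                for lev in levels:
                    cnt = counts[lev]
                    lev_n = (df[group] == lev).sum()
                    row[str(lev)] = f"{cnt} ({100.0 * cnt / lev_n:.2f})"
                rows.append(row)
        else:
            samples = [s[df[group] == lev].to_numpy(dtype=float) for lev in levels]
            if all(np.std(x) == 0 for x in samples):
                stat, p = np.nan, np.nan
            elif len(samples) == 2:
                stat, p = stats.ttest_ind(*samples, equal_var=False)
            else:
                stat, p = stats.f_oneway(*samples)
            row = {"variable": var, "type": "continuous", "statistic": stat, "p": p,
                   "total": f"{s.mean():.2f} ({s.std():.2f})"}
            for lev, x in zip(levels, samples):
                row[str(lev)] = f"{x.mean():.2f} ({x.std(ddof=1):.2f})"
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class PipelineConfig:
    """End-to-end run configuration; exactly one input source must be set."""

    output_dir: str | Path
    input_path: str | Path | None = None
    roles: VariableRoleMap | None = None
    synthetic: SyntheticConfig | None = None
    stratum: str | None = "urban"
    waves: tuple | None = None
    seed: int = 0
    use_weights: bool = True
    decomposition_mode: str = "tertiles"  # or "log_expenditure"
    make_plots: bool = True
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.synthetic is None):
            raise ConfigurationError("set exactly one of input_path / synthetic")
        if self.input_path is not None and self.roles is None:
            raise ConfigurationError("a role map is required with a file input")
        if self.decomposition_mode not in ("tertiles", "log_expenditure"):
            raise ConfigurationError(f"unknown decomposition_mode {self.decomposition_mode!r}")


def _prepare(config: PipelineConfig) -> AnalyticDataset:
    if config.synthetic is not None:
        ds = generate_panel(config.synthetic, seed=config.seed)
    else:
        ds = load_dataset(config.input_path, config.roles)
    if not config.use_weights and ds.roles.weight is not None:
        from dataclasses import replace

        ds = AnalyticDataset(ds.records, replace(ds.roles, weight=None), ds.dropped, ds.meta)
    if config.waves is not None and ds.roles.wave is not None:
        ds = ds.subset(ds.records[ds.roles.wave].isin(list(config.waves)))
    ds = assign_tertiles(ds)
    if config.decomposition_mode == "tertiles":
        ds = add_tertile_dummies(ds)
    else:
        from dataclasses import replace

        df = ds.records.copy()
        pos = df[ds.roles.living_standard] > 0
        dropped_log = int((~pos).sum())
        if dropped_log:
            logger.info("log-expenditure mode: dropping %d non-positive rows", dropped_log)
        df = df.loc[pos].reset_index(drop=True)
        df["log_expenditure"] = np.log(df[ds.roles.living_standard])
        roles = replace(ds.roles, control=ds.roles.control + ("log_expenditure",))
        ds = AnalyticDataset(df, roles, {**ds.dropped, "nonpositive_for_log": dropped_log}, ds.meta)
    return ds


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle; returns the manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "version": __version__,
        "files": [],
        "errors": [],
    }

    def _write(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, index=False, float_format="%.10g")
        manifest["files"].append(name)

    ds = _prepare(config)
    manifest["dropped_rows"] = ds.dropped
    manifest["n_by_wave"] = {str(k): int(v) for k, v in ds.n_by_wave().items()}

    waves = ds.waves() or ["all"]
    by = [c for c in (ds.roles.wave, config.stratum) if c is not None]

    # utilization rates by wave and stratum
    rates = utilization_rates(ds, by or None)
    overall = utilization_rates(ds, [ds.roles.wave] if ds.roles.wave else None)
    _write(rates, "utilization_rates_by_stratum.csv")
    _write(overall, "utilization_rates.csv")

    # descriptive table with group tests, first wave
    if config.stratum is not None:
        first = ds.wave_subset(waves[0]) if ds.roles.wave is not None else ds
        try:
            _write(describe_sample(first, config.stratum), "descriptives.csv")
        except Exception as exc:
            manifest["errors"].append(f"descriptives: {exc}")

    # odds-ratio tables from the year-fixed-effect logit
    try:
        _write(fit_fe_logit(ds, stratum=config.stratum), "or_table.csv")
    except Exception as exc:
        manifest["errors"].append(f"or_table: {exc}")

    # CI, HI and full decompositions per wave x stratum
    ci_rows = []
    strata: list[tuple[str, AnalyticDataset]] = []
    for wave in waves:
        dsw = ds.wave_subset(wave) if ds.roles.wave is not None else ds
        strata = [("total", dsw)]
        if config.stratum is not None:
            for lev in sorted(dsw.records[config.stratum].unique().tolist()):
                strata.append(
                    (f"{config.stratum}={lev}", dsw.subset(dsw.records[config.stratum] == lev))
                )
        for label, sub in strata:
            try:
                # within a stratum, the stratum dummy (and any covariate that
                # happens to be constant there) cannot enter the probit
                from dataclasses import replace

                need = tuple(c for c in sub.roles.need if sub.records[c].nunique() > 1)
                ctrl = tuple(c for c in sub.roles.control if sub.records[c].nunique() > 1)
                dropped_const = sorted(set(sub.roles.regressors) - set(need) - set(ctrl))
                if dropped_const:
                    manifest.setdefault("constant_regressors_dropped", {})[
                        f"{wave}/{label}"
                    ] = dropped_const
                sub = AnalyticDataset(
                    sub.records, replace(sub.roles, need=need, control=ctrl),
                    sub.dropped, sub.meta,
                )
                res = decompose_ci(sub)
            except Exception as exc:
                manifest["errors"].append(f"decomposition {wave}/{label}: {exc}")
                continue
            est = res.total_ci
            ci_rows.append(
                dict(wave=wave, stratum=label, ci=est.value, se=est.se,
                     lower=est.ci95[0], upper=est.ci95[1], hi=res.hi, mu=est.mu, n=est.n)
            )
            dec = res.rows.copy()
            dec.loc[len(dec)] = dict(
                variable="residual", role="", marginal_effect=np.nan, mean=np.nan,
                elasticity=np.nan, variable_ci=np.nan,
                contribution=res.residual_contribution, pct_contribution=res.residual_pct,
            )
            _write(dec, f"decomposition_{wave}_{label.replace('=', '_')}.csv")
    _write(pd.DataFrame(ci_rows), "ci_hi.csv")

    # concentration-curve data and plot
    curve_frames = []
    for wave in waves:
        dsw = ds.wave_subset(wave) if ds.roles.wave is not None else ds
        curve = concentration_curve(dsw.outcome, dsw.living_standard, dsw.weights)
        cf = curve.to_frame()
        cf.insert(0, "wave", wave)
        curve_frames.append(cf)
    curves = pd.concat(curve_frames, ignore_index=True)
    _write(curves, "concentration_curves.csv")
    if config.make_plots:
        try:
            _plot_curves(curves, out / "concentration_curves.png")
            manifest["files"].append("concentration_curves.png")
        except Exception as exc:  # pragma: no cover - plotting backend issues
            manifest["errors"].append(f"plot: {exc}")

    manifest["ok"] = not manifest["errors"]
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _plot_curves(curves: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5.5, 5.5))
    for wave, grp in curves.groupby("wave"):
        ax.plot(grp["population_share"], grp["outcome_share"], label=str(wave), lw=1.2)
    ax.plot([0, 1], [0, 1], "k--", lw=0.8, label="equality")
    ax.set_xlabel("cumulative population share (poorest first)")
    ax.set_ylabel("cumulative share of utilization")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
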