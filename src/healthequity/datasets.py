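"""Analytic dataset container, input validation, and economic-status tertiles.

The analysis operates on person–wave records with declared variable roles:
a binary utilization outcome, a continuous living-standard measure
(per-capita household consumption expenditure net of health expenditure),
need covariates (demographic/health determinants of legitimate need),
control covariates, optional sampling weights and a survey-wave column.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TERTILE_LABELS = ("low", "medium", "high")


class ConfigurationError(ValueError):
    """A role map or config names columns/options that do not exist or clash."""


class ValidationError(ValueError):
    """Input data violate a contract (non-binary outcome, negative weight, ...)."""


@dataclass(frozen=True)
class VariableRoleMap:
    """Mapping from analysis roles to dataset column names.

    Parameters
    ----------
    outcome : str
        Binary (0/1) utilization indicator.
    living_standard : str
        Continuous welfare measure used for ranking (currency units).
    need : tuple of str
        Need covariates (e.g. age-group dummies, sex, disability, chronic
        disease); their contribution to inequality is considered legitimate.
    control : tuple of str
        Non-need covariates (residence, region, education, ...).
    weight : str, optional
        Nonnegative sampling weights; absent means unweighted.
    wave : str, optional
        Survey wave/year column; analyses are per-wave cross-sections.
    """

    outcome: str
    living_standard: str
    need: tuple[str, ...] = ()
    control: tuple[str, ...] = ()
    weight: str | None = None
    wave: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "need", tuple(self.need))
        object.__setattr__(self, "control", tuple(self.control))
        overlap = set(self.need) & set(self.control)
        if overlap:
            raise ConfigurationError(
                f"need and control roles overlap: {sorted(overlap)}"
            )
        reserved = {self.outcome, self.living_standard}
        bad = reserved & (set(self.need) | set(self.control))
        if bad:
            raise ConfigurationError(
                f"outcome/living-standard columns cannot also be need or control: {sorted(bad)}"
            )

    @property
    def regressors(self) -> tuple[str, ...]:
        return self.need + self.control

    def columns(self) -> list[str]:
        cols = [self.outcome, self.living_standard, *self.need, *self.control]
        for optional in (self.weight, self.wave):
            if optional is not None:
                cols.append(optional)
        return cols

    @classmethod
    def from_dict(cls, d: Mapping) -> "VariableRoleMap":
        return cls(
            outcome=d["outcome"],
            living_standard=d["living_standard"],
            need=tuple(d.get("need", ())),
            control=tuple(d.get("control", ())),
            weight=d.get("weight"),
            wave=d.get("wave"),
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "VariableRoleMap":
        """Read a role map from a JSON or YAML config file."""
        text = Path(path).read_text()
        if str(path).endswith((".yml", ".yaml")):
            import yaml

            d = yaml.safe_load(text)
        else:
            d = json.loads(text)
        return cls.from_dict(d)

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "living_standard": self.living_standard,
            "need": list(self.need),
            "control": list(self.control),
            "weight": self.weight,
            "wave": self.wave,
        }


@dataclass(frozen=True)
class TertileCuts:
    """Per-wave tertile cut points (upper bounds of low and medium groups)."""

    wave: object
    lower_cut: float
    upper_cut: float


@dataclass
class AnalyticDataset:
    """Validated person–wave records plus their role map.

    ``records`` holds one row per person–wave; ``dropped`` counts rows removed
    during loading, by reason; ``meta`` carries provenance (generator config,
    tertile cut points, ...).
    """

    records: pd.DataFrame
    roles: VariableRoleMap
    dropped: dict[str, int] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.records)

    def n_by_wave(self) -> pd.Series:
        if self.roles.wave is None:
            return pd.Series({"all": self.n})
        return self.records.groupby(self.roles.wave).size()

    @property
    def outcome(self) -> np.ndarray:
        return self.records[self.roles.outcome].to_numpy(dtype=float)

    @property
    def living_standard(self) -> np.ndarray:
        return self.records[self.roles.living_standard].to_numpy(dtype=float)

    @property
    def weights(self) -> np.ndarray:
        if self.roles.weight is None:
            return np.ones(self.n)
        return self.records[self.roles.weight].to_numpy(dtype=float)

    def waves(self) -> list:
        if self.roles.wave is None:
            return []
        return sorted(self.records[self.roles.wave].unique().tolist())

    def subset(self, mask: np.ndarray | pd.Series) -> "AnalyticDataset":
        sub = self.records.loc[np.asarray(mask, dtype=bool)].reset_index(drop=True)
        return AnalyticDataset(sub, self.roles, dict(self.dropped), dict(self.meta))

    def wave_subset(self, wave) -> "AnalyticDataset":
        if self.roles.wave is None:
            raise ConfigurationError("dataset has no wave column")
        return self.subset(self.records[self.roles.wave] == wave)

    def to_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False)


def load_dataset(path: str | Path, roles: VariableRoleMap) -> AnalyticDataset:
    """Read a delimited text file and validate it against a role map.

    Rows with a missing outcome, a non-finite living standard, or a missing
    weight are dropped and counted by reason; outcome values outside {0, 1}
    or negative weights raise :class:`ValidationError`.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in roles.columns() if c not in df.columns]
    if missing:
        raise ConfigurationError(f"input file lacks role column(s): {missing}")

    raw_n = len(df)
    dropped: dict[str, int] = {}

    y = pd.to_numeric(df[roles.outcome], errors="coerce")
    miss_y = y.isna()
    dropped["missing_outcome"] = int(miss_y.sum())
    df = df.loc[~miss_y].copy()
    y = y.loc[~miss_y]
    offending = sorted(set(y.unique()) - {0.0, 1.0})
    if offending:
        raise ValidationError(
            f"outcome column {roles.outcome!r} must be binary 0/1; found {offending}"
        )
    df[roles.outcome] = y.astype(float)

    ls = pd.to_numeric(df[roles.living_standard], errors="coerce")
    bad_ls = ~np.isfinite(ls.to_numpy(dtype=float))
    dropped["nonfinite_living_standard"] = int(bad_ls.sum())
    df = df.loc[~bad_ls].copy()
    df[roles.living_standard] = ls.loc[~bad_ls].astype(float)

    if roles.weight is not None:
        w = pd.to_numeric(df[roles.weight], errors="coerce")
        miss_w = w.isna()
        dropped["missing_weight"] = int(miss_w.sum())
        df = df.loc[~miss_w].copy()
        w = w.loc[~miss_w]
        if (w < 0).any():
            raise ValidationError(f"weight column {roles.weight!r} has negative values")
        df[roles.weight] = w.astype(float)

    df = df.reset_index(drop=True)
    kept = len(df)
    total_dropped = sum(dropped.values())
    assert kept + total_dropped == raw_n
    if total_dropped:
        logger.info("load_dataset: dropped %d/%d rows (%s)", total_dropped, raw_n, dropped)
    return AnalyticDataset(df, roles, dropped)


def net_expenditure(expenditure, health_expenditure):
    """Consumption expenditure net of health-care expenditure (both per capita).

    The difference may be negative and is retained as-is: the living-standard
    variable only needs to define an ordering for the fractional rank.
    """
    e = np.asarray(expenditure, dtype=float)
    h = np.asarray(health_expenditure, dtype=float)
    if not (np.all(np.isfinite(e)) and np.all(np.isfinite(h))):
        raise ValidationError("expenditure inputs must be finite")
    if np.any(e < 0):
        raise ValidationError("total expenditure must be nonnegative")
    out = e - h
    return float(out) if out.ndim == 0 else out


def _tertile_labels_for(values: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Equal-count tertile labels; ties at a cut all go to the lower group."""
    n = len(values)
    if n < 3:
        raise ValidationError(f"need at least 3 records per wave for tertiles, got {n}")
    order = np.argsort(values, kind="stable")
    s1 = n // 3 + (1 if n % 3 == 2 else 0)
    s2 = n // 3
    srt = values[order]
    lower_cut = float(srt[s1 - 1])
    upper_cut = float(srt[s1 + s2 - 1])
    if upper_cut < lower_cut:  # massive ties pulled medium below low
        upper_cut = lower_cut
    labels = np.where(
        values <= lower_cut, "low", np.where(values <= upper_cut, "medium", "high")
    )
    return labels, lower_cut, upper_cut


def assign_tertiles(
    dataset: AnalyticDataset,
    per_wave: bool = True,
    column: str = "economic_tertile",
) -> AnalyticDataset:
    """Split the living-standard distribution into low/medium/high thirds.

    Group sizes differ by at most 2 before tie resolution; tied values
    straddling a cut are all assigned to the lower group. Cut points are
    stored in ``meta['tertile_cuts']`` as :class:`TertileCuts`.
    """
    df = dataset.records.copy()
    ls = dataset.living_standard
    cuts: list[TertileCuts] = []
    labels = np.empty(len(df), dtype=object)
    if per_wave and dataset.roles.wave is not None:
        for wave, idx in df.groupby(dataset.roles.wave).indices.items():
            lab, lo, hi = _tertile_labels_for(ls[idx])
            labels[idx] = lab
            cuts.append(TertileCuts(wave, lo, hi))
    else:
        lab, lo, hi = _tertile_labels_for(ls)
        labels[:] = lab
        cuts.append(TertileCuts("all", lo, hi))
    df[column] = pd.Categorical(labels, categories=list(TERTILE_LABELS), ordered=True)
    meta = dict(dataset.meta)
    meta["tertile_cuts"] = cuts
    return AnalyticDataset(df, dataset.roles, dict(dataset.dropped), meta)


def add_tertile_dummies(
    dataset: AnalyticDataset,
    column: str = "economic_tertile",
    into_roles: bool = True,
) -> AnalyticDataset:
    """Add 0/1 medium/high tertile dummies (reference: low) as control columns."""
    if column not in dataset.records.columns:
        raise ConfigurationError(f"tertile column {column!r} not present; run assign_tertiles first")
    df = dataset.records.copy()
    df["tertile_medium"] = (df[column] == "medium").astype(float)
    df["tertile_high"] = (df[column] == "high").astype(float)
    roles = dataset.roles
    if into_roles:
        extra = tuple(c for c in ("tertile_medium", "tertile_high") if c not in roles.control)
        roles = replace(roles, control=roles.control + extra)
    return AnalyticDataset(df, roles, dict(dataset.dropped), dict(dataset.meta))
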