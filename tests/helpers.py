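"""Shared construction helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd

from healthequity import AnalyticDataset, VariableRoleMap


def make_dataset(
    outcome,
    living_standard,
    weights=None,
    wave=None,
    extra: dict | None = None,
    need=(),
    control=(),
) -> AnalyticDataset:
    """Build an AnalyticDataset directly from arrays."""
    df = pd.DataFrame(
        {"y": np.asarray(outcome, float), "ls": np.asarray(living_standard, float)}
    )
    kwargs = {}
    if weights is not None:
        df["w"] = np.asarray(weights, float)
        kwargs["weight"] = "w"
    if wave is not None:
        df["wave"] = wave
        kwargs["wave"] = "wave"
    for name, vals in (extra or {}).items():
        df[name] = vals
    roles = VariableRoleMap(
        outcome="y", living_standard="ls", need=tuple(need), control=tuple(control), **kwargs
    )
    return AnalyticDataset(df, roles)


def brute_force_tertiles(values) -> np.ndarray:
    """Plain-Python oracle: positional thirds, tie blocks pulled to the lower group."""
    values = list(map(float, values))
    n = len(values)
    order = sorted(range(n), key=lambda i: (values[i], i))
    s1 = n // 3 + (1 if n % 3 == 2 else 0)
    s2 = n // 3
    labels = {}
    for pos, i in enumerate(order):
        labels[i] = "low" if pos < s1 else ("medium" if pos < s1 + s2 else "high")
    # ties straddling a cut: every record sharing a value takes the lowest label
    rank_of = {"low": 0, "medium": 1, "high": 2}
    for v in set(values):
        idx = [i for i in range(n) if values[i] == v]
        lowest = min((labels[i] for i in idx), key=lambda l: rank_of[l])
        for i in idx:
            labels[i] = lowest
    return np.array([labels[i] for i in range(n)], dtype=object)
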