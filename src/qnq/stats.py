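"""Group comparisons used on regrowth biomass and lag lengths.

One-way ANOVA with Tukey HSD post hoc compares culture-type biomass at
chosen regrowth time points; two-sided t tests (Welch by default) compare
lag lengths between cultures.  Degenerate inputs (all groups identical)
take a defined p = 1 path instead of propagating NaN.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["GroupSample", "anova_tukey", "compare_lags_ttest"]


@dataclass(frozen=True)
class GroupSample:
    """Replicate values (biomass in cells, or lag in hours) for one group."""

    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if len(self.values) < 2:
            raise ValueError(
                f"group {self.label!r} needs >= 2 replicates for variance-based tests"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"group {self.label!r} contains non-finite values")


def anova_tukey(samples: Sequence[GroupSample]) -> tuple[float, float, pd.DataFrame]:
    """One-way ANOVA plus Tukey HSD pairwise comparisons.

    Returns ``(F, p, table)`` where ``table`` has one row per group pair
    with the mean difference and the studentized-range-adjusted p value.
    If every observation is identical the comparison is vacuous: F is
    reported as 0 and all adjusted p values as 1.
    """
    if len(samples) < 2:
        raise ValueError("anova_tukey needs >= 2 groups")
    labels = [s.label for s in samples]
    if len(set(labels)) != len(labels):
        raise ValueError("group labels must be unique")
    arrays = [s.values for s in samples]
    pairs = list(combinations(range(len(samples)), 2))
    all_values = np.concatenate(arrays)
    if np.allclose(all_values, all_values[0]):
        table = pd.DataFrame({
            "group_a": [labels[i] for i, _ in pairs],
            "group_b": [labels[j] for _, j in pairs],
            "mean_diff": 0.0,
            "p_adj": 1.0,
        })
        return 0.0, 1.0, table
    f_stat, p_value = sps.f_oneway(*arrays)
    tukey = sps.tukey_hsd(*arrays)
    table = pd.DataFrame({
        "group_a": [labels[i] for i, _ in pairs],
        "group_b": [labels[j] for _, j in pairs],
        "mean_diff": [float(np.mean(arrays[i]) - np.mean(arrays[j]))
                      for i, j in pairs],
        "p_adj": [float(tukey.pvalue[i, j]) for i, j in pairs],
    })
    return float(f_stat), float(p_value), table


def compare_lags_ttest(a: GroupSample, b: GroupSample,
                       welch: bool = True) -> tuple[float, float, float]:
    """Two-sided two-sample t test on lag lengths.

    Welch's unequal-variance form by default (``welch=False`` pools the
    variances).  Returns ``(t, df, p)``.  Two identical constant groups
    yield ``(0, df, 1)``.
    """
    x, y = a.values, b.values
    if (np.allclose(x, x[0]) and np.allclose(y, y[0])
            and np.isclose(x[0], y[0])):
        df = len(x) + len(y) - 2
        return 0.0, float(df), 1.0
    res = sps.ttest_ind(x, y, equal_var=not welch)
    return float(res.statistic), float(res.df), float(res.pvalue)
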