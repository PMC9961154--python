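"""Morphometrics and group-comparison statistics.

Condition factor (Fulton's K) summarizes nutritional status as
100 * weight / length^3 (g, cm). Endpoint comparisons between genotypes
use an independent-samples t test for two groups and one-way ANOVA with
Tukey HSD for more; results are reported as mean +/- standard error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FishMeasurement",
    "GroupComparison",
    "condition_factor",
    "compare_groups",
]


@dataclass(frozen=True)
class FishMeasurement:
    fish_id: str
    genotype: str
    body_weight: float  # g
    standard_length: float  # cm

    def __post_init__(self) -> None:
        if self.body_weight <= 0 or self.standard_length <= 0:
            raise ValueError("weight and length must be > 0")

    @property
    def condition_factor(self) -> float:
        return condition_factor(self.body_weight, self.standard_length)


def condition_factor(weight: float, length: float) -> float:
    """Fulton's condition factor, 100 * W / L**3 (W in g, L in cm)."""
    if weight <= 0 or length <= 0:
        raise ValueError("weight and length must be > 0")
    return 100.0 * weight / length**3


@dataclass(frozen=True)
class GroupComparison:
    """Result of comparing one endpoint across groups.

    ``test`` is "t" for two groups or "anova+tukey" for more;
    ``pairwise`` holds Tukey-adjusted p-values per group pair (for the
    two-group case it repeats the single t-test p).
    """

    endpoint: str
    test: str
    summary: pd.DataFrame  # group, n, mean, se
    p_value: float
    pairwise: dict[tuple[str, str], float]
    statistic: float


def _mean_se(values: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    rows = []
    for g, v in values.items():
        v = np.asarray(v, dtype=float)
        rows.append(
            {
                "group": g,
                "n": v.size,
                "mean": float(v.mean()),
                "se": float(v.std(ddof=1) / np.sqrt(v.size)),
            }
        )
    return pd.DataFrame(rows)


def compare_groups(
    values: Mapping[str, Sequence[float]],
    endpoint: str = "endpoint",
    equal_var: bool = True,
) -> GroupComparison:
    """Two groups: independent-samples t test (Student by default, Welch
    with ``equal_var=False``). More groups: one-way ANOVA + Tukey HSD."""
    names = list(values)
    arrays = [np.asarray(values[g], dtype=float) for g in names]
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    for g, v in zip(names, arrays):
        if v.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")
    summary = _mean_se(values)
    if len(names) == 2:
        t, p = stats.ttest_ind(arrays[0], arrays[1], equal_var=equal_var)
        return GroupComparison(
            endpoint=endpoint,
            test="t" if equal_var else "welch-t",
            summary=summary,
            p_value=float(p),
            pairwise={(names[0], names[1]): float(p)},
            statistic=float(t),
        )
    f, p = stats.f_oneway(*arrays)
    tukey = stats.tukey_hsd(*arrays)
    pairwise = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            pairwise[(names[i], names[j])] = float(tukey.pvalue[i, j])
    return GroupComparison(
        endpoint=endpoint,
        test="anova+tukey",
        summary=summary,
        p_value=float(p),
        pairwise=pairwise,
        statistic=float(f),
    )
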