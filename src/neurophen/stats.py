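"""Linear density, nerve-fiber summaries, and cohort group statistics.

Linear Purkinje density is manual cell count divided by measured layer
length (cells/mm).  Group comparisons follow the conventions of small-
cohort mouse phenotyping: two-tailed Student's t assuming equal or
unequal variances (the variant is an explicit flag, never an automatic
gate), one-way ANOVA, and Bonferroni correction for families of tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "DensityRecord",
    "GroupTestResult",
    "linear_density",
    "two_sample_t",
    "one_way_anova",
    "bonferroni",
    "nerve_fiber_summary",
    "normal_quantile_table",
]


@dataclass
class DensityRecord:
    """One section's identity, manual count, layer length, and density."""

    sample_id: str
    genotype: str  # WT | KO | HET
    age_months: float
    sex: str
    cell_count: int
    layer_length_mm: float
    density_cells_per_mm: float = field(init=False)

    def __post_init__(self) -> None:
        self.density_cells_per_mm = linear_density(
            self.cell_count, self.layer_length_mm
        )


@dataclass
class GroupTestResult:
    statistic: float
    degrees_of_freedom: float
    p_two_tailed: float
    test_variant: str  # pooled_t | welch_t | anova_F
    group_ns: tuple[int, ...]
    group_means: tuple[float, ...]
    group_sds: tuple[float, ...]
    note: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_two_tailed <= 1.0:
            raise ValueError("p-value outside [0, 1]")
        if self.degrees_of_freedom <= 0:
            raise ValueError("degrees of freedom must be positive")


def linear_density(cell_count: int, layer_length_mm: float) -> float:
    """Cells per mm of measured layer: the exact ratio count / length."""
    if layer_length_mm <= 0:
        raise ValueError("layer length must be positive")
    if cell_count < 0:
        raise ValueError("cell count must be non-negative")
    return cell_count / layer_length_mm


def _summaries(groups) -> tuple[tuple, tuple, tuple]:
    ns = tuple(len(g) for g in groups)
    means = tuple(float(np.mean(g)) for g in groups)
    sds = tuple(float(np.std(g, ddof=1)) for g in groups)
    return ns, means, sds


def two_sample_t(x, y, equal_var: bool = True) -> GroupTestResult:
    """Two-tailed Student's t, pooled-variance or Welch.

    Pooled uses df = n1 + n2 - 2; Welch uses the Welch-Satterthwaite
    df.  Degenerate data (zero variance in both groups with equal
    means) is reported as t = 0, p = 1 with an explanatory note.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 observations")
    ns, means, sds = _summaries([x, y])
    variant = "pooled_t" if equal_var else "welch_t"
    if sds[0] == 0.0 and sds[1] == 0.0:
        if means[0] == means[1]:
            return GroupTestResult(
                statistic=0.0,
                degrees_of_freedom=float(len(x) + len(y) - 2),
                p_two_tailed=1.0,
                test_variant=variant,
                group_ns=ns,
                group_means=means,
                group_sds=sds,
                note="zero variance in both groups with equal means; p=1 by convention",
            )
        raise ValueError("zero variance in both groups with unequal means")
    res = sps.ttest_ind(x, y, equal_var=equal_var)
    return GroupTestResult(
        statistic=float(res.statistic),
        degrees_of_freedom=float(res.df),
        p_two_tailed=float(res.pvalue),
        test_variant=variant,
        group_ns=ns,
        group_means=means,
        group_sds=sds,
    )


def one_way_anova(groups: list) -> GroupTestResult:
    """One-way fixed-effects ANOVA: F = MS_between / MS_within."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs at least 2 observations")
    ns, means, sds = _summaries(groups)
    k, n_total = len(groups), sum(ns)
    df = (float(k - 1), float(n_total - k))
    allv = np.concatenate(groups)
    if np.all(allv == allv[0]):
        return GroupTestResult(
            statistic=0.0,
            degrees_of_freedom=df[1],
            p_two_tailed=1.0,
            test_variant="anova_F",
            group_ns=ns,
            group_means=means,
            group_sds=sds,
            note=f"all values identical; F=0, p=1 by convention; df={df}",
        )
    res = sps.f_oneway(*groups)
    return GroupTestResult(
        statistic=float(res.statistic),
        degrees_of_freedom=df[1],
        p_two_tailed=float(res.pvalue),
        test_variant="anova_F",
        group_ns=ns,
        group_means=means,
        group_sds=sds,
        note=f"df={df}",
    )


def bonferroni(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Bonferroni correction over a family of m tests.

    Returns ``(adjusted_p, reject)`` with ``adjusted_p_i = min(1, m p_i)``
    and rejection when the raw p-value is at or below ``alpha / m``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size < 1:
        raise ValueError("empty p-value family")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    adjusted = np.minimum(1.0, m * p)
    reject = p <= alpha / m
    return adjusted, reject


def nerve_fiber_summary(
    sections: pd.DataFrame,
    group_cols: list[str] | str = "group",
    sample_col: str = "sample_id",
    count_col: str = "fiber_count",
) -> pd.DataFrame:
    """Per-sample section means, then group-level mean +/- SD.

    ``sections`` has one row per counted nerve cross-section.  Section
    counts are first averaged within each sample, and samples of the
    same group (strain, or strain x age) are then summarized as mean
    and sample SD with the number of contributing samples recorded.
    """
    if isinstance(group_cols, str):
        group_cols = [group_cols]
    if sections.empty:
        raise ValueError("empty section table")
    per_sample = (
        sections.groupby(group_cols + [sample_col], sort=True)[count_col]
        .mean()
        .reset_index(name="sample_mean")
    )
    out = (
        per_sample.groupby(group_cols, sort=True)["sample_mean"]
        .agg(n_samples="count", mean="mean", sd=lambda v: v.std(ddof=1))
        .reset_index()
    )
    return out


def normal_quantile_table(values) -> pd.DataFrame:
    """Normal-quantile diagnostic: sorted values vs. theoretical quantiles.

    A descriptive aid for judging normality of fiber counts (plot
    ``theoretical`` against ``observed``); not a hypothesis test.
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    if n < 2:
        raise ValueError("need at least 2 values")
    probs = (np.arange(1, n + 1) - 0.5) / n
    return pd.DataFrame(
        {
            "observed": v,
            "theoretical": sps.norm.ppf(probs, loc=v.mean(), scale=v.std(ddof=1)),
        }
    )
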