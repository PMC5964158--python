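"""Validation statistics: trace agreement (nearest-point distance + ICC) and
one-way repeated-measures ANOVA for systematic displacement."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from repe.core import SulcusTrace
from repe.errors import ParameterError


@dataclass
class TraceAgreement:
    """Agreement between an automatic and a manual trace."""

    mean_dist_mm: float
    sd_dist_mm: float
    icc: float

    def __post_init__(self):
        if self.mean_dist_mm < 0:
            raise ParameterError("mean distance cannot be negative")
        if self.icc > 1 + 1e-12:
            raise ParameterError("ICC cannot exceed 1")


def icc_2_1(data: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``data`` is (n targets, k raters).  Uses the classical mean-square form
        (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n).
    Degenerate all-constant input returns 1.0 (perfect agreement).
    """
    data = np.asarray(data, dtype=float)
    n, k = data.shape
    if n < 2 or k < 2:
        raise ParameterError("ICC needs at least 2 targets and 2 raters")
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ssr = k * ((row_means - grand) ** 2).sum()
    ssc = n * ((col_means - grand) ** 2).sum()
    sst = ((data - grand) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        return 1.0
    return float((msr - mse) / denom)


def trace_agreement(auto: SulcusTrace, manual: SulcusTrace) -> TraceAgreement:
    """Nearest-point distances from auto to manual plus a pooled-coordinate ICC.

    Point counts may differ (manual traces typically have fewer points);
    each auto point is matched to its nearest manual point, and ICC(2,1) is
    computed over the matched coordinate triplets with the three axes pooled.
    """
    tree = cKDTree(manual.points)
    d, idx = tree.query(auto.points)
    matched = manual.points[idx]
    pooled = np.stack(
        [auto.points.reshape(-1), matched.reshape(-1)], axis=1
    )  # (3n, 2): raters = methods
    return TraceAgreement(
        mean_dist_mm=float(d.mean()),
        sd_dist_mm=float(d.std(ddof=1)) if len(d) > 1 else 0.0,
        icc=icc_2_1(pooled),
    )


@dataclass
class AnovaResult:
    """One repeated-measures F test."""

    factor: str
    F: float
    df_num: int
    df_den: int
    p: float

    def __post_init__(self):
        if self.F < 0 or not (0 <= self.p <= 1):
            raise ParameterError("invalid F or p")

    def to_dict(self) -> dict:
        return {
            "factor": self.factor,
            "F": self.F,
            "df_num": self.df_num,
            "df_den": self.df_den,
            "p": self.p,
        }


def rm_anova(data: np.ndarray, factor: str = "condition") -> AnovaResult:
    """One-way repeated-measures ANOVA on a (subjects x conditions) table.

    Standard within-subject decomposition: subject effects are removed, the
    condition mean square is tested against the condition-by-subject residual.
    With two conditions F equals the squared paired t statistic exactly.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ParameterError("rm_anova expects a 2D (subjects x conditions) table")
    n, k = data.shape
    if n < 2 or k < 2:
        raise ParameterError("need >= 2 subjects and >= 2 conditions")
    if not np.all(np.isfinite(data)):
        raise ParameterError("unbalanced table: missing values are not supported")
    grand = data.mean()
    ss_cond = n * ((data.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((data.mean(axis=1) - grand) ** 2).sum()
    ss_tot = ((data - grand) ** 2).sum()
    ss_err = ss_tot - ss_cond - ss_subj
    df_num = k - 1
    df_den = (k - 1) * (n - 1)
    ms_cond = ss_cond / df_num
    ms_err = ss_err / df_den
    if ms_err == 0:
        f = 0.0 if ms_cond == 0 else np.inf
    else:
        f = ms_cond / ms_err
    p = float(stats.f.sf(f, df_num, df_den)) if np.isfinite(f) else 0.0
    return AnovaResult(factor=factor, F=float(f), df_num=df_num, df_den=df_den, p=p)


def rm_anova_table(table: pd.DataFrame) -> list[AnovaResult]:
    """Run one RM-ANOVA per axis on a long-format delta table.

    Expected columns: ``subject``, ``condition``, ``axis``, ``delta_mm``.
    The table must be balanced (every subject x condition x axis cell filled
    exactly once).
    """
    required = {"subject", "condition", "axis", "delta_mm"}
    if not required.issubset(table.columns):
        raise ParameterError(f"table must have columns {sorted(required)}")
    results = []
    for axis, group in table.groupby("axis", sort=True):
        wide = group.pivot_table(
            index="subject", columns="condition", values="delta_mm", aggfunc="count"
        )
        if wide.isna().any().any() or not (wide == 1).all().all():
            raise ParameterError(f"unbalanced table for axis {axis!r}")
        wide = group.pivot(index="subject", columns="condition", values="delta_mm")
        results.append(rm_anova(wide.to_numpy(), factor=f"condition[{axis}]"))
    return results
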