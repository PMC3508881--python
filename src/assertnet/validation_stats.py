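"""Validation statistics: one-way ANOVA (raw and from printed summaries),
Spearman rank correlation, and a Monte-Carlo Lilliefors normality check.

These are the procedures used to validate candidate biomarkers against group
membership (control / MCI / AD) and against a quantitative endophenotype such
as MRI whole-brain volume.  ANOVA-from-summary matters because published
tables report only (n, mean, SD) per group: the between-group sum of squares
is recoverable from group means about the weighted grand mean and the
within-group sum of squares from Σ(nᵢ−1)·sdᵢ², so the F statistic of the
underlying raw data is reproducible exactly from the printed numbers.

The statistics are authored here (they are the replicated procedure);
``scipy.stats`` supplies only reference distributions and rank utilities.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .vocabulary import AssertnetError

__all__ = [
    "StatsError",
    "GroupSummary",
    "AnovaResult",
    "SpearmanResult",
    "NormalityResult",
    "read_measurements",
    "summarize_groups",
    "anova_oneway",
    "anova_from_summary",
    "spearman",
    "normality_check",
]


class StatsError(AssertnetError):
    """Degenerate or invalid statistical input."""


@dataclasses.dataclass(frozen=True)
class GroupSummary:
    """Printed per-group summary: label, n, mean, SD (same arbitrary units)."""

    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise StatsError(f"group {self.label!r}: need n >= 2, got {self.n}")
        if self.sd < 0:
            raise StatsError(f"group {self.label!r}: sd must be >= 0")


@dataclasses.dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float


@dataclasses.dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p: float


@dataclasses.dataclass(frozen=True)
class NormalityResult:
    ks_statistic: float
    p: float
    n_mc: int


def read_measurements(path: str | Path) -> pd.DataFrame:
    """Load a measurement TSV (``subject_id  group  value  [covariate]``)."""
    frame = pd.read_csv(Path(path), sep="\t")
    missing = {"subject_id", "group", "value"} - set(frame.columns)
    if missing:
        raise StatsError(f"{path}: missing columns {sorted(missing)}")
    return frame


def summarize_groups(table: pd.DataFrame) -> list[GroupSummary]:
    """Per-group (n, mean, sample SD), ordered by group label."""
    out = []
    for label, sub in table.groupby("group", sort=True):
        values = np.asarray(sub["value"], dtype=float)
        out.append(
            GroupSummary(str(label), len(values), float(values.mean()),
                         float(values.std(ddof=1)))
        )
    return out


def anova_oneway(table: pd.DataFrame) -> AnovaResult:
    """One-way fixed-effects ANOVA on a raw measurement table.

    Requires ≥2 groups with ≥2 observations each.  When every observation is
    identical, F = 0 and p = 1 by convention; zero within-group variance with
    a real between-group difference is degenerate and raises.
    """
    groups = [
        np.asarray(sub["value"], dtype=float) for _, sub in table.groupby("group")
    ]
    if len(groups) < 2:
        raise StatsError("need at least 2 groups")
    for g in groups:
        if len(g) < 2:
            raise StatsError("every group needs n >= 2")
    values = np.concatenate(groups)
    grand = values.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    return _f_test(float(ss_between), float(ss_within), len(groups), len(values))


def anova_from_summary(groups: Sequence[GroupSummary]) -> AnovaResult:
    """One-way ANOVA recovered exactly from printed (n, mean, SD) summaries."""
    if len(groups) < 2:
        raise StatsError("need at least 2 groups")
    N = sum(g.n for g in groups)
    grand = sum(g.n * g.mean for g in groups) / N
    ss_between = sum(g.n * (g.mean - grand) ** 2 for g in groups)
    ss_within = sum((g.n - 1) * g.sd**2 for g in groups)
    return _f_test(ss_between, ss_within, len(groups), N)


def _f_test(ss_between: float, ss_within: float, k: int, N: int) -> AnovaResult:
    df_b, df_w = k - 1, N - k
    if ss_within <= 0.0:
        if ss_between <= 1e-12:
            return AnovaResult(0.0, df_b, df_w, 1.0)
        raise StatsError(
            "zero within-group variance with non-zero between-group variance; "
            "F is unbounded"
        )
    F = (ss_between / df_b) / (ss_within / df_w)
    return AnovaResult(float(F), df_b, df_w, float(stats.f.sf(F, df_b, df_w)))


# --------------------------------------------------------------------------
# Spearman rank correlation
# --------------------------------------------------------------------------

_EXACT_PERMUTATION_N = 8  # exhaustive permutation p up to here, t approximation above


def _rank_corr(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of average ranks (handles ties)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float((rx**2).sum() * (ry**2).sum()))
    if denom == 0.0:
        raise StatsError("constant input: Spearman rho is undefined")
    return float(np.clip((rx * ry).sum() / denom, -1.0, 1.0))


def spearman(x: Sequence[float], y: Sequence[float]) -> SpearmanResult:
    """Spearman rank correlation with a two-sided p-value.

    Ties receive average ranks.  The p-value is an exhaustive permutation
    test for n ≤ 8 and the usual t approximation
    ``t = rho·sqrt((n−2)/(1−rho²))`` on n−2 df above that.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise StatsError("x and y must be equal-length vectors")
    n = len(x)
    if n < 3:
        raise StatsError("need n >= 3")
    rho = _rank_corr(x, y)
    if n <= _EXACT_PERMUTATION_N:
        # ranking commutes with permutation, so permute centred ranks directly
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        rx = tuple(rx - rx.mean())
        ry = tuple(ry - ry.mean())
        denom = math.sqrt(sum(v * v for v in rx) * sum(v * v for v in ry))
        target = (abs(rho) - 1e-12) * denom
        hits = total = 0
        for perm in itertools.permutations(ry):
            total += 1
            if abs(sum(a * b for a, b in zip(rx, perm))) >= target:
                hits += 1
        return SpearmanResult(rho, hits / total)
    if abs(rho) >= 1.0:
        return SpearmanResult(rho, 0.0)
    t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
    return SpearmanResult(rho, float(2.0 * stats.t.sf(abs(t), n - 2)))


# --------------------------------------------------------------------------
# normality check (Lilliefors-corrected Kolmogorov-Smirnov, Monte-Carlo p)
# --------------------------------------------------------------------------


def _ks_fitted_normal(x: np.ndarray) -> float:
    """KS distance between the empirical CDF and a normal fitted by mean/sd."""
    n = len(x)
    mu = x.mean()
    sd = x.std(ddof=1)
    if sd <= 0:
        raise StatsError("constant sample: normality check is undefined")
    cdf = stats.norm.cdf(np.sort(x), loc=mu, scale=sd)
    upper = np.arange(1, n + 1) / n - cdf
    lower = cdf - np.arange(0, n) / n
    return float(max(upper.max(), lower.max()))


def normality_check(
    x: Sequence[float], n_mc: int = 2000, seed: int = 0
) -> NormalityResult:
    """Test departure from normality when mean and SD are estimated.

    Because the null parameters are fitted from the sample, the classical KS
    reference distribution is wrong (Lilliefors' correction); the p-value is
    therefore estimated by seeded Monte-Carlo: draw ``n_mc`` standard-normal
    samples of the same size, refit, and count KS distances at least as large
    as the observed one (with the +1 continuity adjustment).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 5:
        raise StatsError("need a 1-d sample with n >= 5")
    d_obs = _ks_fitted_normal(x)
    n = len(x)
    rng = np.random.default_rng(seed)
    samples = rng.standard_normal((n_mc, n))
    mu = samples.mean(axis=1, keepdims=True)
    sd = samples.std(ddof=1, axis=1, keepdims=True)
    cdf = stats.norm.cdf((np.sort(samples, axis=1) - mu) / sd)
    grid = np.arange(1, n + 1) / n
    d_mc = np.maximum(
        (grid - cdf).max(axis=1), (cdf - (grid - 1.0 / n)).max(axis=1)
    )
    exceed = int((d_mc >= d_obs).sum())
    return NormalityResult(d_obs, (exceed + 1) / (n_mc + 1), n_mc)
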