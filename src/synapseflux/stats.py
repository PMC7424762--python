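"""Behavioural and survival statistics for fly cohort experiments.

Implements the negative-geotaxis performance index, the Kaplan-Meier
product-limit estimator, the two-group log-rank test, a stratified permutation
test for a genotype x induction interaction on survival, a permutation test on
performance-index differences, and one-way ANOVA with Tukey's HSD.

The log-rank statistic is computed with the standard hypergeometric-variance
formulation over distinct event times:

    chi2 = ( sum_j (O_aj - E_aj) )^2 / sum_j V_j ,   df = 1,

with E_aj = d_j * n_aj / n_j and V_j = d_j (n_aj/n_j)(1 - n_aj/n_j)(n_j - d_j)/(n_j - 1).
It is implemented directly in numpy because the permutation interaction test
evaluates it hundreds of thousands of times.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateTestError, ParameterError

__all__ = [
    "ClimbingCounts",
    "PerformanceIndex",
    "SurvivalRecord",
    "LogRankResult",
    "InteractionTestResult",
    "AnovaResult",
    "performance_index",
    "kaplan_meier",
    "logrank_test",
    "permutation_interaction_test",
    "permutation_pi_test",
    "one_way_anova",
    "records_to_frame",
]


@dataclass(frozen=True)
class ClimbingCounts:
    """Flies counted in the top 5 cm / centre 15 cm / bottom 5 cm after one timed climb."""

    n_top: int
    n_middle: int
    n_bottom: int
    timepoint: str = ""
    genotype: str = ""
    induction: str = ""

    def __post_init__(self) -> None:
        if min(self.n_top, self.n_middle, self.n_bottom) < 0:
            raise ParameterError("bin counts must be >= 0")

    @property
    def total(self) -> int:
        return self.n_top + self.n_middle + self.n_bottom


@dataclass(frozen=True)
class PerformanceIndex:
    value: float
    timepoint: str = ""


@dataclass(frozen=True)
class SurvivalRecord:
    """One fly: genotype, induction condition, and its death (or censoring) day."""

    fly_id: str
    genotype: str
    induction: str
    day: float
    censored: bool = False

    def __post_init__(self) -> None:
        if not self.day > 0:
            raise ParameterError("day must be > 0")


@dataclass(frozen=True)
class LogRankResult:
    chi_square: float
    df: int
    p_value: float


@dataclass(frozen=True)
class InteractionTestResult:
    observed_stat: float
    p_value: float
    n_perm: int


@dataclass(frozen=True)
class AnovaResult:
    f_stat: float
    df_between: int
    df_within: int
    p_value: float
    tukey_pairs: tuple[tuple[tuple[str, str], float, float], ...] = field(default=())


def performance_index(counts: ClimbingCounts) -> PerformanceIndex:
    """Climbing performance index in [0, 1].

    PI = 0.5 * [N_top + N_middle + N_bottom + N_top - N_bottom] / N_total,
    equivalently 0.5 * (1 + (N_top - N_bottom) / N_total): 1 when every fly
    reaches the top bin, 0 when every fly stays at the bottom.
    """
    total = counts.total
    if total < 1:
        raise ParameterError("performance index undefined for zero flies")
    value = 0.5 * (total + counts.n_top - counts.n_bottom) / total
    return PerformanceIndex(value=value, timepoint=counts.timepoint)


def records_to_frame(records: Iterable[SurvivalRecord]) -> pd.DataFrame:
    """Survival records as a DataFrame (fly_id, genotype, induction, day, censored)."""
    rows = list(records)
    if not rows:
        raise ParameterError("no survival records")
    return pd.DataFrame([r.__dict__ for r in rows])


def _days_events(records: Sequence[SurvivalRecord]) -> tuple[np.ndarray, np.ndarray]:
    days = np.array([r.day for r in records], dtype=float)
    events = np.array([not r.censored for r in records], dtype=float)
    if np.any(days <= 0):
        raise ParameterError("all days must be > 0")
    return days, events


def kaplan_meier(records: Sequence[SurvivalRecord]) -> pd.DataFrame:
    """Product-limit survival curve over distinct event days.

    Returns a DataFrame with columns ``time, at_risk, events, censored,
    survival``; the first row is (0, n, 0, 0, 1.0). ``survival`` is the
    right-continuous step value from each time onward. Censored flies leave
    the risk set at their censoring day without an event step.
    """
    if not records:
        raise ParameterError("no survival records")
    days, events = _days_events(records)
    order = np.argsort(days, kind="stable")
    days, events = days[order], events[order]
    times, inverse = np.unique(days, return_inverse=True)
    d = np.bincount(inverse, weights=events)
    c = np.bincount(inverse, weights=1.0 - events)
    removed = d + c
    n_at_risk = days.size - np.concatenate(([0.0], np.cumsum(removed)[:-1]))
    with np.errstate(invalid="ignore"):
        frac = np.where(n_at_risk > 0, 1.0 - d / n_at_risk, 1.0)
    survival = np.cumprod(frac)
    out = pd.DataFrame(
        {
            "time": np.concatenate(([0.0], times)),
            "at_risk": np.concatenate(([float(days.size)], n_at_risk)),
            "events": np.concatenate(([0.0], d)),
            "censored": np.concatenate(([0.0], c)),
            "survival": np.concatenate(([1.0], survival)),
        }
    )
    return out


def _logrank_oe_v(
    days: np.ndarray, events: np.ndarray, in_group_a: np.ndarray
) -> tuple[float, float]:
    """Sum of (O_a - E_a) and of hypergeometric variances over distinct event times."""
    order = np.argsort(days, kind="stable")
    days, events, za = days[order], events[order], in_group_a[order].astype(float)
    times, inverse = np.unique(days, return_inverse=True)
    d = np.bincount(inverse, weights=events)  # total deaths per distinct time
    da = np.bincount(inverse, weights=events * za)  # group-a deaths
    removed = np.bincount(inverse)  # leaves risk set (death or censor)
    removed_a = np.bincount(inverse, weights=za)
    n = days.size - np.concatenate(([0.0], np.cumsum(removed)[:-1].astype(float)))
    na = za.sum() - np.concatenate(([0.0], np.cumsum(removed_a)[:-1]))
    has_event = d > 0
    d, da, n, na = d[has_event], da[has_event], n[has_event], na[has_event]
    frac_a = na / n
    oe = float(np.sum(da - d * frac_a))
    with np.errstate(invalid="ignore", divide="ignore"):
        v = d * frac_a * (1.0 - frac_a) * (n - d) / (n - 1.0)
    v = np.where(n > 1.0, v, 0.0)
    return oe, float(np.sum(v))


def logrank_chi2(days: np.ndarray, events: np.ndarray, in_group_a: np.ndarray) -> float:
    """Two-group log-rank chi-square from parallel day/event/membership arrays.

    Low-level entry point used by the permutation machinery; returns 0.0 when
    the variance degenerates (e.g. one group empties before any event).
    """
    oe, v = _logrank_oe_v(
        np.asarray(days, float), np.asarray(events, float), np.asarray(in_group_a, bool)
    )
    if v <= 0:
        return 0.0
    return oe * oe / v


def logrank_test(
    group_a: Sequence[SurvivalRecord], group_b: Sequence[SurvivalRecord]
) -> LogRankResult:
    """Two-group log-rank test (df = 1) comparing survival of two fly cohorts."""
    if not group_a or not group_b:
        raise ParameterError("both groups need >= 1 record")
    da, ea = _days_events(group_a)
    db, eb = _days_events(group_b)
    if ea.sum() == 0 or eb.sum() == 0:
        raise DegenerateTestError("each group needs >= 1 uncensored event")
    days = np.concatenate([da, db])
    events = np.concatenate([ea, eb])
    membership = np.concatenate([np.ones(da.size, bool), np.zeros(db.size, bool)])
    oe, v = _logrank_oe_v(days, events, membership)
    if v <= 0:
        # identical event structure; no information to compare
        return LogRankResult(chi_square=0.0, df=1, p_value=1.0)
    chi2 = oe * oe / v
    return LogRankResult(chi_square=chi2, df=1, p_value=float(sps.chi2.sf(chi2, 1)))


def _signed_induction_chi2(
    days: np.ndarray, events: np.ndarray, induced: np.ndarray, mask: np.ndarray
) -> float:
    """Induced-vs-uninduced log-rank chi-square within ``mask``, signed by effect direction.

    Positive when the induced arm accumulates more deaths than expected (i.e.
    induction is harmful in this genotype).
    """
    oe, v = _logrank_oe_v(days[mask], events[mask], induced[mask])
    if v <= 0:
        return 0.0
    return float(np.sign(oe)) * oe * oe / v


def permutation_interaction_test(
    records: Sequence[SurvivalRecord],
    n_perm: int = 10_000,
    seed: int | None = None,
) -> InteractionTestResult:
    """Stratified permutation test for a genotype x induction survival interaction.

    The observed statistic is the difference between the two genotypes'
    induced-vs-uninduced log-rank chi-squares, each signed by the direction of
    the induction effect; a nonzero value means induction shifts survival more
    in one genotype than the other. The null distribution is built by
    permuting genotype labels within induction strata (induction-specific
    effects common to both genotypes are preserved; genotype-specific
    responses are broken). Two-sided p with the add-one rule:
    p = (1 + #{|T_perm| >= |T_obs|}) / (1 + n_perm), never exactly 0.
    """
    if n_perm < 1:
        raise ParameterError("n_perm must be >= 1")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a coarse permutation p-value", stacklevel=2)
    if seed is None:
        raise ParameterError("a seed is required for reproducible permutation tests")
    rows = list(records)
    genotypes = sorted({r.genotype for r in rows})
    inductions = sorted({r.induction for r in rows})
    if len(genotypes) != 2 or len(inductions) != 2:
        raise ParameterError("the design must have exactly 2 genotypes x 2 induction levels")
    for g in genotypes:
        for i in inductions:
            if not any(r.genotype == g and r.induction == i for r in rows):
                raise ParameterError(f"empty design cell: genotype={g}, induction={i}")

    days, events = _days_events(rows)
    geno_a = np.array([r.genotype == genotypes[0] for r in rows])
    induced = np.array([r.induction == inductions[1] for r in rows])

    def stat(geno_mask: np.ndarray) -> float:
        return _signed_induction_chi2(days, events, induced, geno_mask) - _signed_induction_chi2(
            days, events, induced, ~geno_mask
        )

    observed = stat(geno_a)
    rng = np.random.default_rng(seed)
    strata = [np.flatnonzero(~induced), np.flatnonzero(induced)]
    exceed = 0
    work = geno_a.copy()
    for _ in range(n_perm):
        for idx in strata:
            work[idx] = geno_a[idx][rng.permutation(idx.size)]
        if abs(stat(work)) >= abs(observed):
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return InteractionTestResult(observed_stat=float(observed), p_value=float(p), n_perm=n_perm)


def permutation_pi_test(
    counts_a: Sequence[ClimbingCounts],
    counts_b: Sequence[ClimbingCounts],
    n_perm: int = 10_000,
    seed: int | None = None,
) -> InteractionTestResult:
    """Permutation test for a genotype difference in climbing performance index.

    ``counts_a`` and ``counts_b`` hold one trial per matched timepoint for each
    genotype. The statistic is the mean over timepoints of PI_a - PI_b; the
    null reshuffles flies between the two genotypes within each timepoint
    (multivariate hypergeometric draws on the pooled bin counts), preserving
    the timepoint-specific pooled climbing ability. Two-sided, add-one rule.
    """
    if len(counts_a) != len(counts_b) or not counts_a:
        raise ParameterError("need equal, non-empty per-timepoint count lists")
    if seed is None:
        raise ParameterError("a seed is required for reproducible permutation tests")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a coarse permutation p-value", stacklevel=2)

    def mean_pi_diff(pairs: Sequence[tuple[ClimbingCounts, ClimbingCounts]]) -> float:
        return float(
            np.mean([performance_index(a).value - performance_index(b).value for a, b in pairs])
        )

    observed = mean_pi_diff(list(zip(counts_a, counts_b)))
    rng = np.random.default_rng(seed)
    pooled = [
        (
            np.array([a.n_top + b.n_top, a.n_middle + b.n_middle, a.n_bottom + b.n_bottom]),
            a.total,
        )
        for a, b in zip(counts_a, counts_b)
    ]
    exceed = 0
    for _ in range(n_perm):
        diffs = []
        for bins, n_a in pooled:
            draw_a = rng.multivariate_hypergeometric(bins, n_a)
            rest = bins - draw_a
            pa = performance_index(ClimbingCounts(*[int(v) for v in draw_a]))
            pb = performance_index(ClimbingCounts(*[int(v) for v in rest]))
            diffs.append(pa.value - pb.value)
        if abs(float(np.mean(diffs))) >= abs(observed):
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return InteractionTestResult(observed_stat=observed, p_value=float(p), n_perm=n_perm)


def one_way_anova(
    groups: Mapping[str, Sequence[float]] | Sequence[Sequence[float]],
) -> AnovaResult:
    """One-way ANOVA with Tukey HSD post-hoc pairwise comparisons.

    ``groups`` maps condition label to measurements (a bare sequence of groups
    gets labels g0..gk-1). F = MS_between / MS_within with df (k-1, N-k);
    Tukey-adjusted p-values come from the studentized-range distribution.
    """
    if not isinstance(groups, Mapping):
        groups = {f"g{i}": g for i, g in enumerate(groups)}
    labels = list(groups)
    data = [np.asarray(groups[k], dtype=float) for k in labels]
    if len(data) < 2:
        raise ParameterError("need >= 2 groups")
    for lab, arr in zip(labels, data):
        if arr.size < 2:
            raise ParameterError(f"group {lab!r} needs n >= 2")
        if not np.all(np.isfinite(arr)):
            raise ParameterError(f"group {lab!r} has non-finite values")
    k = len(data)
    n_total = int(sum(a.size for a in data))
    values = np.concatenate(data)
    cond = np.concatenate([np.repeat(lab, a.size) for lab, a in zip(labels, data)])
    if np.all(values == values[0]):
        # all observations identical: MS_between = 0, F = 0, no pairwise differences
        pairs = tuple(
            ((labels[i], labels[j]), 0.0, 1.0) for i in range(k) for j in range(i + 1, k)
        )
        return AnovaResult(0.0, k - 1, n_total - k, 1.0, pairs)
    f_stat, p_value = sps.f_oneway(*data)
    if not np.isfinite(f_stat):  # zero within-group variance, unequal means
        raise ParameterError("ANOVA undefined: zero within-group variance")

    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    tk = pairwise_tukeyhsd(values, cond)
    pairs = tuple(
        ((str(row[0]), str(row[1])), float(row[2]), float(row[3]))
        for row in tk.summary().data[1:]
    )
    return AnovaResult(
        f_stat=float(f_stat),
        df_between=k - 1,
        df_within=n_total - k,
        p_value=float(p_value),
        tukey_pairs=pairs,
    )
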