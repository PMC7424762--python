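"""Independent brute-force oracles used to validate the fast implementations.

These are deliberately slow, literal transcriptions of the scoring rules,
written frame-by-frame (detector) or table-by-table (log-rank, ANOVA) with no
code shared with the package.
"""

from __future__ import annotations

import math
from typing import Sequence


# --- event detection -------------------------------------------------------

def _prev_distinct(x: Sequence[float], i: int):
    j = i - 1
    while j >= 0 and x[j] == x[i]:
        j -= 1
    return None if j < 0 else x[j]


def _next_distinct(x: Sequence[float], i: int):
    j = i + 1
    while j < len(x) and x[j] == x[i]:
        j += 1
    return None if j >= len(x) else x[j]


def _plateau_first(x: Sequence[float], i: int) -> bool:
    return i == 0 or x[i - 1] != x[i]


def _is_local_max(x: Sequence[float], i: int) -> bool:
    if not _plateau_first(x, i):
        return False
    pv, nv = _prev_distinct(x, i), _next_distinct(x, i)
    return (pv is None or pv < x[i]) and (nv is None or nv < x[i])


def brute_force_transients(
    x: Sequence[float], threshold: float = 0.1, offset_band: float = 0.2
) -> list[dict]:
    """Literal frame-by-frame execution of the event/burst segmentation rules.

    Returns dicts with onset, peak frames/values, offset, burst flag, scored
    amplitude and truncation flag.
    """
    x = [float(v) for v in x]
    n = len(x)
    out: list[dict] = []
    i = 0
    while i < n:
        if not (_is_local_max(x, i) and x[i] > threshold):
            i += 1
            continue
        onset = i
        while onset > 0 and x[onset - 1] <= x[onset]:
            onset -= 1
        peaks = [i]
        offset = None
        j = i + 1
        while j < n:
            pv = _prev_distinct(x, j)
            falling = _plateau_first(x, j) and pv is not None and x[j] < pv
            if falling and x[j] - x[onset] <= offset_band:
                offset = j
                break
            if _is_local_max(x, j) and x[j] > threshold:
                peaks.append(j)
            j += 1
        truncated = False
        if offset is None:
            offset = n - 1
            lf = n - 1
            while lf > 0 and x[lf - 1] == x[lf]:
                lf -= 1
            truncated = _is_local_max(x, lf) and lf in peaks
            i = n
        else:
            i = offset + 1
        out.append(
            {
                "onset": onset,
                "peaks": tuple(peaks),
                "peak_values": tuple(x[p] for p in peaks),
                "offset": offset,
                "is_burst": len(peaks) >= 2,
                "scored": max(x[p] for p in peaks),
                "truncated": truncated,
            }
        )
    return out


# --- two-group log-rank ----------------------------------------------------

def brute_force_logrank(
    days_a: Sequence[float],
    events_a: Sequence[bool],
    days_b: Sequence[float],
    events_b: Sequence[bool],
) -> float:
    """O/E/V tabulation over distinct event times, written with explicit loops."""
    event_times = sorted(
        {d for d, e in zip(days_a, events_a) if e}
        | {d for d, e in zip(days_b, events_b) if e}
    )
    oe_sum = 0.0
    v_sum = 0.0
    for t in event_times:
        na = sum(1 for d in days_a if d >= t)
        nb = sum(1 for d in days_b if d >= t)
        da = sum(1 for d, e in zip(days_a, events_a) if e and d == t)
        db = sum(1 for d, e in zip(days_b, events_b) if e and d == t)
        ntot, dtot = na + nb, da + db
        if ntot == 0:
            continue
        expected_a = dtot * na / ntot
        oe_sum += da - expected_a
        if ntot > 1:
            v_sum += dtot * (na / ntot) * (nb / ntot) * (ntot - dtot) / (ntot - 1)
    return oe_sum * oe_sum / v_sum


# --- one-way ANOVA ---------------------------------------------------------

def brute_force_anova_f(groups: Sequence[Sequence[float]]) -> tuple[float, int, int]:
    """F statistic from explicit sum-of-squares tabulation."""
    all_vals = [v for g in groups for v in g]
    grand = sum(all_vals) / len(all_vals)
    ss_between = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ss_within = sum(sum((v - sum(g) / len(g)) ** 2 for v in g) for g in groups)
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    return (ss_between / df_b) / (ss_within / df_w), df_b, df_w


# --- Kaplan-Meier ----------------------------------------------------------

def brute_force_km(days: Sequence[float], events: Sequence[bool]) -> list[tuple[float, float]]:
    """(time, survival) step values at distinct observed days, by hand."""
    s = 1.0
    out = []
    for t in sorted(set(days)):
        at_risk = sum(1 for d in days if d >= t)
        deaths = sum(1 for d, e in zip(days, events) if e and d == t)
        if at_risk > 0:
            s *= 1.0 - deaths / at_risk
        out.append((t, s))
    return out
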