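"""Glutamate event detection on iGluSnFR fluorescence traces.

The analysis chain converts a raw per-ROI fluorescence trace to deltaF/F
(normalised to the minimum recorded fluorescence), detects supra-threshold
glutamate transients, segments multi-peak bursts, and summarises amplitude and
event rate per trace and per animal.

Detection semantics (all on discrete frames; plateaus of equal values are
collapsed to their first frame):

* a *candidate peak* is a local maximum with deltaF/F above ``event_threshold``
  (default 0.1);
* a transient's *onset* is the first frame of the maximal monotone
  non-decreasing run leading up to its first peak;
* scanning forward from a peak, the transient *offsets* at the first frame of
  the falling phase whose deltaF/F has come back within ``offset_band``
  (default 0.2) of the value at onset, or at the final frame;
* consecutive peaks with no qualifying offset between them form one *burst*,
  scored by its highest peak.

A transient still rising at the final frame is closed there and flagged
``truncated``; truncated transients count toward event rates but are excluded
from amplitude means because their true peak is unobserved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import AmbiguityError, NonPositiveBaselineError, ParameterError

__all__ = [
    "FluorescenceTrace",
    "DffTrace",
    "DetectionParams",
    "GlutamateTransient",
    "TraceSummary",
    "compute_dff",
    "detect_transients",
    "summarize_trace",
    "aggregate_by_animal",
    "match_onsets",
]

#: Frame rate of the live-imaging acquisitions, frames per second.
DEFAULT_FRAME_RATE_HZ = 0.92


@dataclass(frozen=True)
class FluorescenceTrace:
    """Raw fluorescence samples for one ROI at a fixed frame rate."""

    samples: np.ndarray
    frame_rate_hz: float = DEFAULT_FRAME_RATE_HZ
    roi_id: str = "roi0"
    animal_id: str = "animal0"
    condition: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1 or samples.size < 2:
            raise ParameterError("a trace needs >= 2 samples in one dimension")
        if not np.all(np.isfinite(samples)):
            raise ParameterError("trace samples must be finite")
        if self.frame_rate_hz <= 0:
            raise ParameterError("frame_rate_hz must be > 0")
        object.__setattr__(self, "samples", samples)

    @property
    def n_frames(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz


@dataclass(frozen=True)
class DffTrace:
    """deltaF/F trace: (F_t - F0)/F0 with F0 the minimum recorded fluorescence."""

    dff: np.ndarray
    f0: float
    frame_rate_hz: float = DEFAULT_FRAME_RATE_HZ
    roi_id: str = "roi0"
    animal_id: str = "animal0"
    condition: str = ""

    def __post_init__(self) -> None:
        dff = np.asarray(self.dff, dtype=float)
        if dff.ndim != 1 or dff.size < 2:
            raise ParameterError("a dff trace needs >= 2 samples")
        if not np.all(np.isfinite(dff)):
            raise ParameterError("dff values must be finite")
        if self.f0 <= 0:
            raise ParameterError("f0 must be > 0")
        if self.frame_rate_hz <= 0:
            raise ParameterError("frame_rate_hz must be > 0")
        object.__setattr__(self, "dff", dff)

    @property
    def n_frames(self) -> int:
        return int(self.dff.size)

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.frame_rate_hz


@dataclass(frozen=True)
class DetectionParams:
    """Thresholds of the event detector, both in deltaF/F units.

    ``event_threshold``: minimum deltaF/F a local maximum must exceed to count
    as a glutamate event. ``offset_band``: a falling-phase local minimum ends
    the transient when it comes within this distance of the onset value.
    ``smooth_window``: optional centred moving-average width in frames applied
    before detection; 1 disables smoothing (the default — the published
    procedure uses none).
    """

    event_threshold: float = 0.1
    offset_band: float = 0.2
    smooth_window: int = 1

    def __post_init__(self) -> None:
        if self.event_threshold <= 0 or self.offset_band <= 0:
            raise ParameterError("event_threshold and offset_band must be > 0")
        if self.smooth_window < 1:
            raise ParameterError("smooth_window must be >= 1")


@dataclass(frozen=True)
class GlutamateTransient:
    """One detected glutamate event or burst."""

    onset_frame: int
    peak_frames: tuple[int, ...]
    peak_values: tuple[float, ...]
    offset_frame: int
    is_burst: bool
    scored_amplitude: float
    truncated: bool = False

    def __post_init__(self) -> None:
        if not self.peak_frames:
            raise ParameterError("a transient needs >= 1 peak")
        if list(self.peak_frames) != sorted(set(self.peak_frames)):
            raise ParameterError("peak_frames must be strictly increasing")
        if not (self.onset_frame <= self.peak_frames[0] <= self.peak_frames[-1] <= self.offset_frame):
            raise ParameterError("onset <= first peak <= last peak <= offset violated")
        if self.is_burst != (len(self.peak_frames) >= 2):
            raise ParameterError("is_burst must reflect >= 2 peaks")


@dataclass(frozen=True)
class TraceSummary:
    """Per-trace amplitude and event-rate summary."""

    animal_id: str
    condition: str
    roi_id: str
    mean_amplitude: float  # NaN when no (non-truncated) transients
    events_per_min: float
    n_transients: int
    duration_min: float


def compute_dff(trace: FluorescenceTrace) -> DffTrace:
    """Normalise a raw trace to deltaF/F = (F_t - F0)/F0, F0 = min over the trace.

    Raises :class:`NonPositiveBaselineError` if any sample is <= 0, since the
    minimum-fluorescence baseline must be strictly positive.
    """
    f = trace.samples
    f0 = float(f.min())
    if f0 <= 0:
        raise NonPositiveBaselineError(
            f"minimum fluorescence {f0} is not positive; cannot form deltaF/F"
        )
    return DffTrace(
        dff=(f - f0) / f0,
        f0=f0,
        frame_rate_hz=trace.frame_rate_hz,
        roi_id=trace.roi_id,
        animal_id=trace.animal_id,
        condition=trace.condition,
    )


def _run_length_encode(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse consecutive equal values; return (first-frame indices, values)."""
    keep = np.empty(x.size, dtype=bool)
    keep[0] = True
    np.not_equal(x[1:], x[:-1], out=keep[1:])
    starts = np.flatnonzero(keep)
    return starts, x[starts]


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x
    kernel = np.full(window, 1.0 / window)
    pad = window // 2
    padded = np.pad(x, pad, mode="edge")
    out = np.convolve(padded, kernel, mode="valid")
    return out[: x.size]


def detect_transients(
    dff: DffTrace | Sequence[float] | np.ndarray,
    params: DetectionParams | None = None,
) -> list[GlutamateTransient]:
    """Detect glutamate transients (single events and bursts) in a deltaF/F trace.

    Accepts a :class:`DffTrace` or a bare sequence of deltaF/F values. Returns
    disjoint transients in temporal order (adjacent transients may share the
    trough frame that closes one and opens the next).
    """
    if params is None:
        params = DetectionParams()
    x = dff.dff if isinstance(dff, DffTrace) else np.asarray(dff, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ParameterError("dff must be a non-empty 1-D sequence")
    if not np.all(np.isfinite(x)):
        raise ParameterError("dff values must be finite")
    x = _smooth(x, params.smooth_window)

    starts, values = _run_length_encode(x)
    n_runs = starts.size
    last_frame = x.size - 1

    # extremum classification on the collapsed runs; trace boundaries count
    higher_prev = np.empty(n_runs, dtype=bool)
    higher_next = np.empty(n_runs, dtype=bool)
    higher_prev[0] = True
    higher_next[-1] = True
    if n_runs > 1:
        np.greater(values[1:], values[:-1], out=higher_prev[1:])
        np.greater(values[:-1], values[1:], out=higher_next[:-1])
    is_max = higher_prev & higher_next
    is_peak = is_max & (values > params.event_threshold)

    transients: list[GlutamateTransient] = []
    k = 0
    while k < n_runs:
        if not is_peak[k]:
            k += 1
            continue
        # onset: walk back frame-wise through the monotone non-decreasing run
        onset = int(starts[k])
        while onset > 0 and x[onset - 1] <= x[onset]:
            onset -= 1
        onset_value = x[onset]

        peak_runs = [k]
        offset_frame: int | None = None
        truncated = False
        j = k + 1
        while j < n_runs:
            # offset: first falling frame whose value is back within the band
            # of the onset value (plateaus collapse to their first frame)
            if values[j] < values[j - 1] and values[j] - onset_value <= params.offset_band:
                offset_frame = int(starts[j])
                break
            if is_peak[j]:
                peak_runs.append(j)
            j += 1
        if offset_frame is None:
            offset_frame = last_frame
            truncated = bool(is_max[n_runs - 1] and peak_runs[-1] == n_runs - 1)
            j = n_runs  # consumed to the end

        peak_frames = tuple(int(starts[r]) for r in peak_runs)
        peak_values = tuple(float(values[r]) for r in peak_runs)
        transients.append(
            GlutamateTransient(
                onset_frame=onset,
                peak_frames=peak_frames,
                peak_values=peak_values,
                offset_frame=offset_frame,
                is_burst=len(peak_frames) >= 2,
                scored_amplitude=float(max(peak_values)),
                truncated=truncated,
            )
        )
        k = j + 1  # resume after the closing minimum
    return transients


def summarize_trace(
    transients: Iterable[GlutamateTransient],
    dff: DffTrace,
    amplitude_source: str = "all",
) -> TraceSummary:
    """Summarise one trace: mean scored amplitude and events per minute.

    ``amplitude_source`` selects which transients enter the amplitude mean:
    ``"all"`` (default) pools single events and bursts; ``"bursts"`` restricts
    to multi-peak bursts. Truncated transients never contribute to the mean
    (their peak is unobserved) but always count toward the event rate.
    """
    if amplitude_source not in ("all", "bursts"):
        raise ParameterError("amplitude_source must be 'all' or 'bursts'")
    if dff.frame_rate_hz <= 0:
        raise ParameterError("frame rate must be > 0")
    transients = list(transients)
    duration_min = dff.duration_s / 60.0
    scored = [
        t.scored_amplitude
        for t in transients
        if not t.truncated and (amplitude_source == "all" or t.is_burst)
    ]
    mean_amp = float(np.mean(scored)) if scored else math.nan
    n = len(transients)
    return TraceSummary(
        animal_id=dff.animal_id,
        condition=dff.condition,
        roi_id=dff.roi_id,
        mean_amplitude=mean_amp,
        events_per_min=n / duration_min,
        n_transients=n,
        duration_min=duration_min,
    )


def aggregate_by_animal(summaries: Iterable[TraceSummary]) -> pd.DataFrame:
    """Collapse ROI-level summaries to one row per animal.

    Amplitude is the mean of the animal's ROI-level mean amplitudes (ROIs with
    no measurable transient are skipped); event rate is pooled (total
    transients over total recorded minutes). Output columns:
    ``animal_id, condition, mean_amplitude, events_per_min, n_transients,
    n_rois``, grouped by condition for downstream ANOVA.
    """
    rows = list(summaries)
    if not rows:
        raise ParameterError("no summaries to aggregate")
    keys = [(s.animal_id, s.roi_id) for s in rows]
    if len(set(keys)) != len(keys):
        raise AmbiguityError("duplicate (animal_id, roi_id) summaries")
    df = pd.DataFrame([s.__dict__ for s in rows])
    conditions = df.groupby("animal_id")["condition"].nunique()
    if (conditions > 1).any():
        raise AmbiguityError("an animal appears under more than one condition")

    def _one(group: pd.DataFrame) -> pd.Series:
        amps = group["mean_amplitude"].dropna()
        return pd.Series(
            {
                "condition": group["condition"].iloc[0],
                "mean_amplitude": amps.mean() if len(amps) else math.nan,
                "events_per_min": group["n_transients"].sum() / group["duration_min"].sum(),
                "n_transients": int(group["n_transients"].sum()),
                "n_rois": len(group),
            }
        )

    out = df.groupby("animal_id", sort=True).apply(_one, include_groups=False)
    out = out.reset_index().sort_values(["condition", "animal_id"]).reset_index(drop=True)
    out["n_transients"] = out["n_transients"].astype(int)
    out["n_rois"] = out["n_rois"].astype(int)
    return out


def match_onsets(
    true_onsets: Sequence[int],
    detected_onsets: Sequence[int],
    tol_frames: int = 2,
) -> list[tuple[int, int]]:
    """Greedily match ground-truth onsets to detected onsets within a frame tolerance.

    Both lists are taken in temporal order; each detected onset is consumed by
    at most one truth. Returns (truth index, detected index) pairs — the basis
    for recall/precision in detector-recovery studies.
    """
    pairs: list[tuple[int, int]] = []
    used: set[int] = set()
    for i, t in enumerate(true_onsets):
        best: int | None = None
        best_dist = tol_frames + 1
        for j, d in enumerate(detected_onsets):
            if j in used:
                continue
            dist = abs(int(d) - int(t))
            if dist < best_dist:
                best, best_dist = j, dist
        if best is not None:
            pairs.append((i, best))
            used.add(best)
    return pairs
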