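"""Synthetic data with known ground truth for every analysis stage.

Four generators emulate the data the pipeline consumes:

* :func:`simulate_trace` — per-ROI iGluSnFR fluorescence traces with transient
  glutamate events (single and bursting), Gaussian frame noise and optional
  exponential photobleaching; every emitted event is logged with its onset and
  peak structure so detector recovery is measurable.
* :func:`simulate_survival` — fly cohorts in a 2x2 genotype x induction design
  with multiplicative (proportional-hazards) effects on a Weibull or
  exponential baseline.
* :func:`simulate_climbing` — trinomial top/middle/bottom bin counts for timed
  negative-geotaxis trials.
* :func:`simulate_stack` — confocal-like image stacks: a uniform background, a
  brighter ROI, per-slice integer jitter and Gaussian pixel noise, with the
  true shifts returned.

Every generator is a pure function of (params, seed): identical inputs give
bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
import numpy as np

from .errors import ParameterError
from .stats import ClimbingCounts, SurvivalRecord
from .trace_events import DEFAULT_FRAME_RATE_HZ, FluorescenceTrace

__all__ = [
    "TraceSimParams",
    "GroundTruthEvent",
    "SurvivalSimParams",
    "ClimbingSimParams",
    "StackSimParams",
    "simulate_trace",
    "simulate_survival",
    "simulate_climbing",
    "simulate_stack",
]

#: deltaF/F floor applied to simulated event amplitudes so that every logged
#: event clears the 0.1 detection threshold with margin.
MIN_EVENT_AMPLITUDE = 0.15
#: extra amplitude floor for burst sub-peaks: keeps inter-peak troughs well
#: above the 0.2 burst-continuity band given the default decay constant.
MIN_BURST_SUBPEAK_AMPLITUDE = 0.45
#: frames between consecutive burst sub-peaks.
BURST_PEAK_SPACING = 2


@dataclass(frozen=True)
class TraceSimParams:
    """Parameters of the fluorescence-trace simulator.

    ``amplitude_mean``/``amplitude_sd`` are in deltaF/F units relative to
    baseline; ``noise_sd`` is Gaussian frame noise, also in deltaF/F units
    (scaled by the baseline when added to the raw trace). ``bleach_rate`` is
    the per-frame exponential bleaching rate of the baseline (0 disables).
    ``decay_tau_s`` is the exponential decay constant of each transient after
    its linear rise over ``rise_frames`` frames.
    """

    n_frames: int = 25
    frame_rate_hz: float = DEFAULT_FRAME_RATE_HZ
    baseline_f0: float = 100.0
    event_rate_per_min: float = 6.0
    amplitude_mean: float = 0.5
    amplitude_sd: float = 0.1
    burst_prob: float = 0.3
    subpeaks_range: tuple[int, int] = (2, 4)
    decay_tau_s: float = 0.5
    rise_frames: int = 2
    noise_sd: float = 0.02
    bleach_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ParameterError("n_frames must be >= 2")
        if self.frame_rate_hz <= 0:
            raise ParameterError("frame_rate_hz must be > 0")
        if self.baseline_f0 <= 0:
            raise ParameterError("baseline_f0 must be > 0")
        if self.event_rate_per_min < 0 or self.noise_sd < 0 or self.bleach_rate < 0:
            raise ParameterError("rates and noise_sd must be >= 0")
        if self.amplitude_mean <= 0 or self.amplitude_sd < 0:
            raise ParameterError("amplitude_mean must be > 0 and amplitude_sd >= 0")
        if not 0.0 <= self.burst_prob <= 1.0:
            raise ParameterError("burst_prob must be in [0, 1]")
        lo, hi = self.subpeaks_range
        if lo < 2 or hi < lo:
            raise ParameterError("subpeaks_range must be a pair of counts >= 2 with lo <= hi")
        if self.decay_tau_s <= 0 or self.rise_frames < 1:
            raise ParameterError("decay_tau_s must be > 0 and rise_frames >= 1")


@dataclass(frozen=True)
class GroundTruthEvent:
    """Ground-truth log entry for one simulated event (single or burst)."""

    onset_frame: int
    peak_frames: tuple[int, ...]
    peak_amplitudes: tuple[float, ...]
    is_burst: bool

    def __post_init__(self) -> None:
        if list(self.peak_frames) != sorted(set(self.peak_frames)):
            raise ParameterError("peak_frames must be strictly increasing")
        if self.is_burst != (len(self.peak_frames) >= 2):
            raise ParameterError("is_burst must reflect >= 2 peaks")
        if any(a < 0 for a in self.peak_amplitudes):
            raise ParameterError("peak amplitudes must be >= 0")


def _kernel(amplitude: float, rise_frames: int, decay_per_frame: float, length: int) -> np.ndarray:
    """Linear rise to ``amplitude`` over ``rise_frames`` frames, then exponential decay."""
    t = np.arange(length, dtype=float)
    rise = amplitude * t / rise_frames
    decay = amplitude * np.exp(-decay_per_frame * (t - rise_frames))
    return np.where(t <= rise_frames, rise, decay)


def _local_maxima(w: np.ndarray) -> tuple[list[int], list[float]]:
    """Strict local maxima of a short waveform (plateaus to first frame)."""
    frames: list[int] = []
    values: list[float] = []
    n = w.size
    i = 0
    while i < n:
        j = i
        while j + 1 < n and w[j + 1] == w[i]:
            j += 1
        left_ok = i == 0 or w[i - 1] < w[i]
        right_ok = j == n - 1 or w[j + 1] < w[i]
        if left_ok and right_ok and w[i] > 0:
            frames.append(i)
            values.append(float(w[i]))
        i = j + 1
    return frames, values


def simulate_trace(params: TraceSimParams) -> tuple[FluorescenceTrace, list[GroundTruthEvent]]:
    """Simulate one raw fluorescence trace plus its ground-truth event log.

    The raw trace is ``F_t = baseline_f0 * exp(-bleach_rate*t) * (1 + s_t)
    + baseline_f0 * N(0, noise_sd)`` where ``s_t`` sums the deltaF/F transient
    kernels. The number of events is Poisson in the trace duration at
    ``event_rate_per_min``; events are placed without overlap (a minimum
    separation of one transient support), so at high rates the realised count
    can fall below the Poisson draw. Burst sub-peaks are spaced
    ``BURST_PEAK_SPACING`` frames apart with amplitudes floored at
    ``MIN_BURST_SUBPEAK_AMPLITUDE`` so the composed trough between peaks stays
    above the burst-continuity band. Ground truth records the local maxima of
    each event's composed noiseless waveform.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_frames
    dt = 1.0 / params.frame_rate_hz
    decay_per_frame = dt / params.decay_tau_s
    duration_min = n * dt / 60.0

    # event specs
    n_events = int(rng.poisson(params.event_rate_per_min * duration_min))
    specs = []
    for _ in range(n_events):
        is_burst = bool(rng.random() < params.burst_prob)
        n_sub = int(rng.integers(params.subpeaks_range[0], params.subpeaks_range[1] + 1)) if is_burst else 1
        amps = rng.normal(params.amplitude_mean, params.amplitude_sd, n_sub)
        floor = MIN_BURST_SUBPEAK_AMPLITUDE if is_burst else MIN_EVENT_AMPLITUDE
        amps = np.maximum(amps, floor)
        specs.append((n_sub, amps))

    # per-event span: rise + burst extent + decay tail to ~2% of amplitude
    tail = int(math.ceil(params.decay_tau_s / dt * math.log(50.0)))
    spans = [
        params.rise_frames + (n_sub - 1) * BURST_PEAK_SPACING + tail for n_sub, _ in specs
    ]
    min_gap = 3  # baseline frames between consecutive events

    # greedy non-overlapping placement of onsets
    onsets_all = np.sort(rng.integers(1, max(2, n - 1), size=n_events)) if n_events else np.array([], int)
    signal = np.zeros(n)
    events: list[GroundTruthEvent] = []
    cursor = 1
    for onset, (n_sub, amps), span in zip(onsets_all, specs, spans):
        onset = int(max(onset, cursor))
        if onset + span >= n:
            continue
        w = np.zeros(span + 1)
        for i_sub in range(n_sub):
            sub_onset = i_sub * BURST_PEAK_SPACING
            seg_len = span + 1 - sub_onset
            w[sub_onset:] += _kernel(float(amps[i_sub]), params.rise_frames, decay_per_frame, seg_len)
        peak_fr, peak_val = _local_maxima(w)
        signal[onset : onset + span + 1] += w
        events.append(
            GroundTruthEvent(
                onset_frame=onset,
                peak_frames=tuple(onset + f for f in peak_fr),
                peak_amplitudes=tuple(peak_val),
                is_burst=len(peak_fr) >= 2,
            )
        )
        cursor = onset + span + min_gap

    t = np.arange(n, dtype=float)
    bleach = np.exp(-params.bleach_rate * t)
    raw = params.baseline_f0 * bleach * (1.0 + signal)
    if params.noise_sd > 0:
        raw = raw + params.baseline_f0 * rng.normal(0.0, params.noise_sd, n)
    trace = FluorescenceTrace(samples=raw, frame_rate_hz=params.frame_rate_hz)
    return trace, events


@dataclass(frozen=True)
class SurvivalSimParams:
    """2x2 genotype x induction survival cohorts under proportional hazards.

    The first genotype and induction labels appearing in ``groups`` are the
    reference levels; ``genotype_hr``, ``induction_hr`` and ``interaction_hr``
    multiply the baseline hazard for the non-reference genotype, the induced
    condition, and their combination respectively. ``family`` is ``"weibull"``
    (default, shape ``weibull_shape``; sigmoidal fly-like survivorship) or
    ``"exponential"``.
    """

    n_per_group: int = 150
    groups: tuple[tuple[str, str], ...] = (
        ("wt", "RU0"),
        ("wt", "RU200"),
        ("tg", "RU0"),
        ("tg", "RU200"),
    )
    baseline_scale: float = 60.0
    genotype_hr: float = 1.0
    induction_hr: float = 1.0
    interaction_hr: float = 1.0
    censor_day: float | None = None
    family: str = "weibull"
    weibull_shape: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ParameterError("n_per_group must be >= 1")
        if not self.groups:
            raise ParameterError("groups must be non-empty")
        if min(self.genotype_hr, self.induction_hr, self.interaction_hr) <= 0:
            raise ParameterError("hazard ratios must be > 0")
        if self.baseline_scale <= 0:
            raise ParameterError("baseline_scale must be > 0")
        if self.censor_day is not None and self.censor_day <= 0:
            raise ParameterError("censor_day must be > 0")
        if self.family not in ("weibull", "exponential"):
            raise ParameterError("family must be 'weibull' or 'exponential'")
        if self.weibull_shape <= 0:
            raise ParameterError("weibull_shape must be > 0")

    def hazard_ratio(self, genotype: str, induction: str) -> float:
        """Multiplicative hazard ratio of one design cell relative to baseline."""
        ref_geno = self.groups[0][0]
        ref_ind = self.groups[0][1]
        hr = 1.0
        nonref_geno = genotype != ref_geno
        nonref_ind = induction != ref_ind
        if nonref_geno:
            hr *= self.genotype_hr
        if nonref_ind:
            hr *= self.induction_hr
        if nonref_geno and nonref_ind:
            hr *= self.interaction_hr
        return hr


def simulate_survival(params: SurvivalSimParams) -> list[SurvivalRecord]:
    """Draw death days per group from the proportional-hazards parametric family.

    With cumulative baseline hazard H0 and cell hazard ratio ``hr``, a death
    time solves ``hr * H0(T) = E`` with ``E ~ Exp(1)``; for the Weibull family
    ``T = scale * (E/hr)^(1/shape)``. Records past ``censor_day`` are censored
    at that day.
    """
    rng = np.random.default_rng(params.seed)
    shape = params.weibull_shape if params.family == "weibull" else 1.0
    records: list[SurvivalRecord] = []
    for genotype, induction in params.groups:
        hr = params.hazard_ratio(genotype, induction)
        e = rng.exponential(1.0, params.n_per_group)
        t = params.baseline_scale * (e / hr) ** (1.0 / shape)
        for i, ti in enumerate(t):
            day = float(ti)
            censored = False
            if params.censor_day is not None and day > params.censor_day:
                day, censored = float(params.censor_day), True
            records.append(
                SurvivalRecord(
                    fly_id=f"{genotype}_{induction}_{i:04d}",
                    genotype=genotype,
                    induction=induction,
                    day=max(day, 1e-9),
                    censored=censored,
                )
            )
    return records


@dataclass(frozen=True)
class ClimbingSimParams:
    """Trinomial negative-geotaxis trials: ``n_flies`` split into three bins."""

    n_flies: int = 50
    p_top: float = 0.4
    p_middle: float = 0.4
    p_bottom: float = 0.2
    n_trials: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_flies < 1:
            raise ParameterError("n_flies must be >= 1")
        if self.n_trials < 1:
            raise ParameterError("n_trials must be >= 1")
        p = (self.p_top, self.p_middle, self.p_bottom)
        if min(p) < 0 or max(p) > 1:
            raise ParameterError("probabilities must be in [0, 1]")
        if abs(sum(p) - 1.0) > 1e-12:
            raise ParameterError("bin probabilities must sum to 1")


def simulate_climbing(params: ClimbingSimParams) -> list[ClimbingCounts]:
    """One trinomial draw of flies into (top, middle, bottom) per trial."""
    rng = np.random.default_rng(params.seed)
    draws = rng.multinomial(
        params.n_flies, (params.p_top, params.p_middle, params.p_bottom), size=params.n_trials
    )
    return [
        ClimbingCounts(
            n_top=int(d[0]), n_middle=int(d[1]), n_bottom=int(d[2]), timepoint=f"t{i}"
        )
        for i, d in enumerate(draws)
    ]


@dataclass(frozen=True)
class StackSimParams:
    """Confocal-like Z-stack: uniform background plus a brighter ROI, with jitter."""

    n_slices: int = 10
    height: int = 64
    width: int = 64
    roi_mask: np.ndarray | None = None  # boolean (height, width); default central block
    roi_intensity: float = 100.0
    background_intensity: float = 10.0
    noise_sd: float = 0.0
    jitter_px: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_slices < 1 or self.height < 1 or self.width < 1:
            raise ParameterError("n_slices, height, width must be >= 1")
        if self.background_intensity < 0 or self.noise_sd < 0 or self.jitter_px < 0:
            raise ParameterError("intensities, noise_sd, jitter_px must be >= 0")
        if self.roi_intensity < self.background_intensity:
            raise ParameterError("roi_intensity must be >= background_intensity")
        if self.roi_mask is not None:
            mask = np.asarray(self.roi_mask, dtype=bool)
            if mask.shape != (self.height, self.width):
                raise ParameterError("roi_mask dimensions must match height x width")
            object.__setattr__(self, "roi_mask", mask)

    def resolved_mask(self) -> np.ndarray:
        if self.roi_mask is not None:
            return self.roi_mask
        mask = np.zeros((self.height, self.width), dtype=bool)
        h4, w4 = self.height // 4, self.width // 4
        mask[h4 : self.height - h4, w4 : self.width - w4] = True
        return mask


def _translate(img: np.ndarray, dy: int, dx: int, fill: float) -> np.ndarray:
    """Shift image content down/right by (dy, dx); vacated pixels get ``fill``."""
    out = np.full_like(img, fill)
    h, w = img.shape
    ys = slice(max(dy, 0), min(h, h + dy))
    xs = slice(max(dx, 0), min(w, w + dx))
    ys_src = slice(max(-dy, 0), min(h, h - dy))
    xs_src = slice(max(-dx, 0), min(w, w - dx))
    out[ys, xs] = img[ys_src, xs_src]
    return out


def simulate_stack(params: StackSimParams) -> tuple[np.ndarray, np.ndarray]:
    """Simulate an image stack with per-slice integer jitter; returns (stack, shifts).

    The first slice is unshifted by convention; ``shifts[s] = (dy, dx)`` is the
    translation applied to slice ``s`` relative to the canonical image.
    Vacated pixels take the background intensity.
    """
    rng = np.random.default_rng(params.seed)
    mask = params.resolved_mask()
    base = np.full((params.height, params.width), params.background_intensity, dtype=float)
    base[mask] += params.roi_intensity
    shifts = np.zeros((params.n_slices, 2), dtype=int)
    if params.jitter_px > 0 and params.n_slices > 1:
        shifts[1:] = rng.integers(-params.jitter_px, params.jitter_px + 1, size=(params.n_slices - 1, 2))
    stack = np.stack(
        [
            _translate(base, int(dy), int(dx), params.background_intensity)
            for dy, dx in shifts
        ]
    )
    if params.noise_sd > 0:
        stack = stack + rng.normal(0.0, params.noise_sd, stack.shape)
        stack = np.clip(stack, 0.0, None)
    return stack, shifts
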