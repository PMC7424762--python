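"""CSV / TIFF readers and writers for the pipeline's tabular and image formats.

Tabular formats:

* traces: ``frame, roi_id, animal_id, condition, fluorescence``
* ground-truth events: ``animal_id, roi_id, onset_frame, peak_frames,
  peak_amplitudes, is_burst`` (list columns are ``;``-joined)
* transients: one row per detected transient with all fields
* survival: ``fly_id, genotype, induction, day, censored`` (censored 0/1)
* climbing: ``timepoint, genotype, induction, n_top, n_middle, n_bottom``

Stacks are multi-page TIFFs (0-based slice index, row-major pixels); masks are
single-page TIFFs where nonzero pixels are inside the ROI.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import ParameterError
from .stats import ClimbingCounts, SurvivalRecord
from .synthetic import GroundTruthEvent
from .trace_events import FluorescenceTrace, GlutamateTransient, TraceSummary

__all__ = [
    "write_traces_csv",
    "read_traces_csv",
    "write_ground_truth_csv",
    "read_ground_truth_csv",
    "write_transients_csv",
    "write_summaries_csv",
    "write_survival_csv",
    "read_survival_csv",
    "write_climbing_csv",
    "read_climbing_csv",
    "write_stack_tiff",
    "read_stack_tiff",
    "read_mask_tiff",
]


def write_traces_csv(traces: Iterable[FluorescenceTrace], path: str | Path) -> None:
    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "frame": np.arange(tr.n_frames),
                    "roi_id": tr.roi_id,
                    "animal_id": tr.animal_id,
                    "condition": tr.condition,
                    "fluorescence": tr.samples,
                }
            )
        )
    if not frames:
        raise ParameterError("no traces to write")
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_traces_csv(path: str | Path, frame_rate_hz: float) -> list[FluorescenceTrace]:
    df = pd.read_csv(path)
    required = {"frame", "roi_id", "animal_id", "condition", "fluorescence"}
    missing = required - set(df.columns)
    if missing:
        raise ParameterError(f"trace CSV missing columns: {sorted(missing)}")
    for col in ("roi_id", "animal_id", "condition"):
        df[col] = df[col].fillna("").astype(str)
    traces = []
    for (animal, roi, cond), grp in df.groupby(["animal_id", "roi_id", "condition"], sort=True):
        grp = grp.sort_values("frame")
        traces.append(
            FluorescenceTrace(
                samples=grp["fluorescence"].to_numpy(float),
                frame_rate_hz=frame_rate_hz,
                roi_id=str(roi),
                animal_id=str(animal),
                condition=str(cond),
            )
        )
    return traces


def _join(values: Sequence) -> str:
    return ";".join(str(v) for v in values)


def write_ground_truth_csv(
    events: Mapping[tuple[str, str], Sequence[GroundTruthEvent]], path: str | Path
) -> None:
    """``events`` maps (animal_id, roi_id) to that trace's ground-truth log."""
    rows = []
    for (animal, roi), evs in events.items():
        for ev in evs:
            rows.append(
                {
                    "animal_id": animal,
                    "roi_id": roi,
                    "onset_frame": ev.onset_frame,
                    "peak_frames": _join(ev.peak_frames),
                    "peak_amplitudes": _join(ev.peak_amplitudes),
                    "is_burst": int(ev.is_burst),
                }
            )
    pd.DataFrame(
        rows,
        columns=["animal_id", "roi_id", "onset_frame", "peak_frames", "peak_amplitudes", "is_burst"],
    ).to_csv(path, index=False)


def read_ground_truth_csv(path: str | Path) -> dict[tuple[str, str], list[GroundTruthEvent]]:
    df = pd.read_csv(path)
    out: dict[tuple[str, str], list[GroundTruthEvent]] = {}
    for _, row in df.iterrows():
        key = (str(row["animal_id"]), str(row["roi_id"]))
        out.setdefault(key, []).append(
            GroundTruthEvent(
                onset_frame=int(row["onset_frame"]),
                peak_frames=tuple(int(v) for v in str(row["peak_frames"]).split(";")),
                peak_amplitudes=tuple(float(v) for v in str(row["peak_amplitudes"]).split(";")),
                is_burst=bool(int(row["is_burst"])),
            )
        )
    return out


def write_transients_csv(
    transients: Mapping[tuple[str, str], Sequence[GlutamateTransient]], path: str | Path
) -> None:
    rows = []
    for (animal, roi), ts in transients.items():
        for t in ts:
            rows.append(
                {
                    "animal_id": animal,
                    "roi_id": roi,
                    "onset_frame": t.onset_frame,
                    "peak_frames": _join(t.peak_frames),
                    "peak_values": _join(t.peak_values),
                    "offset_frame": t.offset_frame,
                    "is_burst": int(t.is_burst),
                    "scored_amplitude": t.scored_amplitude,
                    "truncated": int(t.truncated),
                }
            )
    pd.DataFrame(
        rows,
        columns=[
            "animal_id",
            "roi_id",
            "onset_frame",
            "peak_frames",
            "peak_values",
            "offset_frame",
            "is_burst",
            "scored_amplitude",
            "truncated",
        ],
    ).to_csv(path, index=False)


def write_summaries_csv(summaries: Iterable[TraceSummary], path: str | Path) -> None:
    pd.DataFrame([s.__dict__ for s in summaries]).to_csv(path, index=False)


def write_survival_csv(records: Iterable[SurvivalRecord], path: str | Path) -> None:
    df = pd.DataFrame([r.__dict__ for r in records])
    df["censored"] = df["censored"].astype(int)
    # %.17g keeps float64 day values exactly round-trippable
    df.to_csv(path, index=False, float_format="%.17g")


def read_survival_csv(path: str | Path) -> list[SurvivalRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"fly_id", "genotype", "induction", "day", "censored"}
    missing = required - set(df.columns)
    if missing:
        raise ParameterError(f"survival CSV missing columns: {sorted(missing)}")
    return [
        SurvivalRecord(
            fly_id=str(r.fly_id),
            genotype=str(r.genotype),
            induction=str(r.induction),
            day=float(r.day),
            censored=bool(int(r.censored)),
        )
        for r in df.itertuples()
    ]


def write_climbing_csv(counts: Iterable[ClimbingCounts], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "timepoint": c.timepoint,
                "genotype": c.genotype,
                "induction": c.induction,
                "n_top": c.n_top,
                "n_middle": c.n_middle,
                "n_bottom": c.n_bottom,
            }
            for c in counts
        ]
    ).to_csv(path, index=False)


def read_climbing_csv(path: str | Path) -> list[ClimbingCounts]:
    df = pd.read_csv(path)
    required = {"timepoint", "n_top", "n_middle", "n_bottom"}
    missing = required - set(df.columns)
    if missing:
        raise ParameterError(f"climbing CSV missing columns: {sorted(missing)}")
    return [
        ClimbingCounts(
            n_top=int(r.n_top),
            n_middle=int(r.n_middle),
            n_bottom=int(r.n_bottom),
            timepoint=str(r.timepoint),
            genotype=str(getattr(r, "genotype", "")),
            induction=str(getattr(r, "induction", "")),
        )
        for r in df.itertuples()
    ]


def write_stack_tiff(stack: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(path, np.asarray(stack))


def read_stack_tiff(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None, ...]
    return np.asarray(arr, dtype=float)


def read_mask_tiff(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(path)
    if arr.ndim != 2:
        raise ParameterError("mask TIFF must be single-page")
    return np.asarray(arr) != 0
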