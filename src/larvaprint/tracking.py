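"""Δ-pixel tracking data: containers, CSV io, and day/night epoch segmentation.

The locomotor signal is "Δ pixels": per well and per frame transition, the
number of camera pixels whose grey value changed beyond the acquisition
sensitivity threshold. Values are therefore non-negative and already
thresholded when they reach this package. Recordings run on a light:dark
cycle; all timing is expressed in Zeitgeber time (ZT), hours since lights-ON.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "LightSchedule",
    "DeltaPixelTrace",
    "TrackingDataset",
    "Epoch",
    "read_tracking",
    "write_tracking",
    "read_schedule",
    "write_schedule",
    "segment_epochs",
]


@dataclass(frozen=True)
class LightSchedule:
    """A 24 h light:dark cycle anchored at lights-ON (ZT0).

    Parameters
    ----------
    day_hours, night_hours : float
        Lit and dark portions of the cycle; must sum to 24. The default
        14:10 cycle is the standard larval-zebrafish behavior rig setting.
    zt0_clock : str, optional
        Wall-clock time of lights-ON, kept only as metadata.
    """

    day_hours: float = 14.0
    night_hours: float = 10.0
    zt0_clock: str | None = None

    def __post_init__(self) -> None:
        if self.day_hours <= 0 or self.night_hours <= 0:
            raise ValueError("day_hours and night_hours must be positive")
        if abs(self.day_hours + self.night_hours - 24.0) > 1e-9:
            raise ValueError(
                f"day_hours + night_hours must equal 24, got "
                f"{self.day_hours + self.night_hours}"
            )

    def phase_at(self, zt: float) -> Literal["day", "night"]:
        return "day" if (zt % 24.0) < self.day_hours else "night"


@dataclass
class DeltaPixelTrace:
    """Per-well frame series of Δ-pixel values."""

    well_id: str
    values: np.ndarray
    fps: float
    start_zt: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError(f"trace {self.well_id!r}: values must be a non-empty 1-d array")
        if self.fps <= 0:
            raise ValueError(f"trace {self.well_id!r}: fps must be positive")
        neg = np.flatnonzero(self.values < 0)
        if neg.size:
            raise ValueError(
                f"trace {self.well_id!r}: negative Δ-pixel value at frame {neg[0]}"
            )

    @property
    def n_frames(self) -> int:
        return int(self.values.size)

    @property
    def duration_hours(self) -> float:
        return self.n_frames / self.fps / 3600.0


@dataclass
class TrackingDataset:
    """One plate: a frames × wells Δ-pixel matrix with group labels.

    ``traces`` is a DataFrame whose columns are well ids; ``groups`` maps
    every well id to its group label (genotype, treatment, ...). All wells
    share ``fps`` and ``start_zt``.
    """

    traces: pd.DataFrame
    groups: pd.Series
    fps: float
    schedule: LightSchedule = field(default_factory=LightSchedule)
    start_zt: float = 0.0

    def __post_init__(self) -> None:
        self.traces = self.traces.astype(float)
        self.groups = pd.Series(self.groups)
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.traces.shape[0] < 1:
            raise ValueError("traces must contain at least one frame")
        if self.traces.isna().any().any():
            well = self.traces.columns[self.traces.isna().any()][0]
            frame = int(self.traces[well].isna().idxmax())
            raise ValueError(f"missing value (ragged column?) at frame {frame}, well {well!r}")
        bad = self.traces.lt(0)
        if bad.any().any():
            well = self.traces.columns[bad.any()][0]
            frame = int(bad[well].idxmax())
            raise ValueError(f"negative Δ-pixel value at frame {frame}, well {well!r}")
        unlabeled = [w for w in self.traces.columns if w not in self.groups.index]
        if unlabeled:
            raise ValueError(f"wells without a group label: {unlabeled}")
        self.groups = self.groups.loc[list(self.traces.columns)]

    @property
    def wells(self) -> list[str]:
        return list(self.traces.columns)

    @property
    def n_frames(self) -> int:
        return int(self.traces.shape[0])

    @property
    def duration_hours(self) -> float:
        return self.n_frames / self.fps / 3600.0

    def trace(self, well_id: str) -> DeltaPixelTrace:
        return DeltaPixelTrace(
            well_id=well_id,
            values=self.traces[well_id].to_numpy(),
            fps=self.fps,
            start_zt=self.start_zt,
        )

    def iter_traces(self) -> Iterator[DeltaPixelTrace]:
        for well in self.traces.columns:
            yield self.trace(well)


@dataclass(frozen=True)
class Epoch:
    """A day or night span of the recording, as a half-open frame range."""

    label: Literal["day", "night"]
    ordinal: int
    start: int
    end: int
    complete: bool = True

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("epoch frame range must be non-empty")

    @property
    def n_frames(self) -> int:
        return self.end - self.start


def _zt_to_frame(zt: float, start_zt: float, fps: float) -> int:
    """Frame index of a ZT boundary; half-up rounding with float guard."""
    return int(math.floor((zt - start_zt) * 3600.0 * fps + 0.5 + 1e-9))


def segment_epochs(
    dataset: TrackingDataset,
    use: Literal["full_epochs_only", "all"] = "full_epochs_only",
) -> list[Epoch]:
    """Tile the recording into day/night epochs on the Zeitgeber clock.

    Epochs are half-open frame ranges; a light transition frame belongs to
    the epoch it starts. With ``use="full_epochs_only"`` epochs truncated by
    the recording start or end are dropped; with ``"all"`` the epochs tile
    the whole recording.
    """
    if use not in ("full_epochs_only", "all"):
        raise ValueError(f"unknown use mode {use!r}")
    sched = dataset.schedule
    zt_start = dataset.start_zt
    zt_end = zt_start + dataset.duration_hours
    n_frames = dataset.n_frames

    # nominal schedule windows [lo, hi) covering the recording
    windows: list[tuple[str, float, float]] = []
    k = math.floor(zt_start / 24.0) - 1
    while 24.0 * k < zt_end + 24.0:
        d0 = 24.0 * k
        windows.append(("day", d0, d0 + sched.day_hours))
        windows.append(("night", d0 + sched.day_hours, d0 + 24.0))
        k += 1

    epochs: list[Epoch] = []
    counters = {"day": 0, "night": 0}
    for label, lo, hi in windows:
        clip_lo, clip_hi = max(lo, zt_start), min(hi, zt_end)
        if clip_hi - clip_lo <= 1e-9:
            continue
        f0 = max(0, _zt_to_frame(clip_lo, zt_start, dataset.fps))
        f1 = min(n_frames, _zt_to_frame(clip_hi, zt_start, dataset.fps))
        if f1 <= f0:
            continue
        complete = lo >= zt_start - 1e-9 and hi <= zt_end + 1e-9
        if use == "full_epochs_only" and not complete:
            continue
        counters[label] += 1
        epochs.append(Epoch(label=label, ordinal=counters[label], start=f0, end=f1, complete=complete))
    return epochs


# ---------------------------------------------------------------------------
# io: wide trace CSV + well metadata CSV + YAML schedule


def read_tracking(
    trace_path: str | Path,
    metadata_path: str | Path,
    schedule: LightSchedule | None = None,
    *,
    fps: float = 1.0,
    start_zt: float = 0.0,
) -> TrackingDataset:
    """Read a plate from a wide CSV (header = well ids, one row per frame)
    and a metadata CSV with columns ``well_id,group``."""
    traces = pd.read_csv(trace_path)
    meta = pd.read_csv(metadata_path, dtype=str)
    if "well_id" not in meta.columns or "group" not in meta.columns:
        raise ValueError("metadata CSV must have columns well_id,group")
    groups = meta.set_index("well_id")["group"]
    if groups.index.has_duplicates:
        dup = groups.index[groups.index.duplicated()][0]
        raise ValueError(f"duplicate well_id in metadata: {dup!r}")
    return TrackingDataset(
        traces=traces,
        groups=groups,
        fps=fps,
        schedule=schedule if schedule is not None else LightSchedule(),
        start_zt=start_zt,
    )


def write_tracking(
    dataset: TrackingDataset, trace_path: str | Path, metadata_path: str | Path
) -> None:
    dataset.traces.to_csv(trace_path, index=False)
    meta = pd.DataFrame(
        {"well_id": dataset.groups.index, "group": dataset.groups.to_numpy()}
    )
    meta.to_csv(metadata_path, index=False)


def read_schedule(path: str | Path) -> LightSchedule:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return LightSchedule(
        day_hours=float(raw.get("day_hours", 14)),
        night_hours=float(raw.get("night_hours", 10)),
        zt0_clock=raw.get("zt0_clock"),
    )


def write_schedule(schedule: LightSchedule, path: str | Path) -> None:
    doc = {"day_hours": schedule.day_hours, "night_hours": schedule.night_hours}
    if schedule.zt0_clock is not None:
        doc["zt0_clock"] = schedule.zt0_clock
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
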