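"""Active/inactive bout decomposition and the nine behavioral parameters.

A frame is *active* when its Δ-pixel value is strictly greater than the
activity floor (default 0; the acquisition rig applies its own sensitivity
threshold before the data reach this package). A *bout* is a maximal run of
consecutive same-state frames. Nine parameters summarize each day or night
epoch:

1. active bout length (s)          6. active bout maximum
2. active bout mean (Δ px)         7. number of active bouts
3. active bout standard deviation  8. total time active (% of epoch)
4. active bout total (sum Δ px)    9. inactive bout length (s)
5. active bout minimum

Per-bout statistics are averaged (unweighted) across the bouts of the epoch;
epochs with no bout of the relevant state report those measures as missing
(NaN), never as 0. Day values average across all day epochs of the recording
and likewise for night, giving an 18-measure vector per larva.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .tracking import DeltaPixelTrace, Epoch, TrackingDataset, segment_epochs

__all__ = [
    "PARAMETERS",
    "MEASURES",
    "BoutSeries",
    "segment_bouts",
    "epoch_parameters",
    "larva_parameters",
    "BoutParameterExtractor",
]

#: the nine per-epoch behavioral parameters, in canonical order
PARAMETERS: tuple[str, ...] = (
    "active_bout_length_s",
    "active_bout_mean",
    "active_bout_std",
    "active_bout_total",
    "active_bout_min",
    "active_bout_max",
    "n_active_bouts",
    "time_active_pct",
    "inactive_bout_length_s",
)

#: canonical 18-measure fingerprint schema: day block then night block
MEASURES: tuple[str, ...] = tuple(f"day_{p}" for p in PARAMETERS) + tuple(
    f"night_{p}" for p in PARAMETERS
)

_ACTIVE_ONLY = (
    "active_bout_length_s",
    "active_bout_mean",
    "active_bout_std",
    "active_bout_total",
    "active_bout_min",
    "active_bout_max",
)


@dataclass
class BoutSeries:
    """Run-length decomposition of a frame range into alternating bouts.

    ``bouts`` is an ordered list of ``(state, start, end)`` with half-open
    frame ranges (indices relative to the original trace) that tile the
    segmented range; states strictly alternate.
    """

    bouts: list[tuple[str, int, int]]
    values: np.ndarray  # the full trace values the ranges index into
    fps: float
    start: int
    end: int

    def __iter__(self):
        return iter(self.bouts)

    def __len__(self) -> int:
        return len(self.bouts)

    def active_bouts(self) -> list[tuple[int, int]]:
        return [(s, e) for st, s, e in self.bouts if st == "active"]

    def inactive_bouts(self) -> list[tuple[int, int]]:
        return [(s, e) for st, s, e in self.bouts if st == "inactive"]


def segment_bouts(
    trace: DeltaPixelTrace | np.ndarray | Sequence[float],
    frame_range: tuple[int, int] | None = None,
    activity_floor: float = 0.0,
    fps: float | None = None,
) -> BoutSeries:
    """Decompose a frame range into maximal active/inactive runs.

    Parameters
    ----------
    trace
        A :class:`~larvaprint.tracking.DeltaPixelTrace` or a plain array of
        Δ-pixel values (then ``fps`` must be given).
    frame_range
        Half-open ``(start, end)``; defaults to the whole trace.
    activity_floor
        A frame is active iff its value is strictly greater than this.
    """
    if isinstance(trace, DeltaPixelTrace):
        values = trace.values
        if fps is None:
            fps = trace.fps
    else:
        values = np.asarray(trace, dtype=float)
        if fps is None:
            raise ValueError("fps is required when passing a raw array")
    if activity_floor < 0:
        raise ValueError("activity_floor must be non-negative")
    start, end = frame_range if frame_range is not None else (0, values.size)
    if not (0 <= start < end <= values.size):
        raise ValueError(f"empty or out-of-bounds frame range ({start}, {end})")

    active = values[start:end] > activity_floor
    # run boundaries: positions where the state changes
    change = np.flatnonzero(active[1:] != active[:-1]) + 1
    edges = np.concatenate(([0], change, [active.size]))
    bouts = [
        ("active" if active[lo] else "inactive", start + int(lo), start + int(hi))
        for lo, hi in zip(edges[:-1], edges[1:])
    ]
    return BoutSeries(bouts=bouts, values=values, fps=fps, start=start, end=end)


def epoch_parameters(bouts: BoutSeries, epoch: Epoch | None = None) -> dict[str, float]:
    """The nine parameters of one epoch from its bout decomposition.

    ``epoch`` (if given) must match the range ``bouts`` was computed on; it
    is accepted for interface symmetry and checked, not re-segmented.
    """
    if epoch is not None and (epoch.start != bouts.start or epoch.end != bouts.end):
        raise ValueError(
            f"bout series covers [{bouts.start}, {bouts.end}) but epoch is "
            f"[{epoch.start}, {epoch.end})"
        )
    n_epoch_frames = bouts.end - bouts.start
    values, fps = bouts.values, bouts.fps

    act = bouts.active_bouts()
    inact = bouts.inactive_bouts()
    out: dict[str, float] = {}

    n_active_frames = sum(e - s for s, e in act)
    out["n_active_bouts"] = float(len(act))
    out["time_active_pct"] = 100.0 * n_active_frames / n_epoch_frames

    if act:
        starts = np.array([s for s, _ in act])
        ends = np.array([e for _, e in act])
        lens = (ends - starts).astype(float)
        # per-bout reductions in one pass: interleave starts/ends as reduceat
        # boundaries, keep the segments that begin at bout starts
        seg = np.empty(2 * len(starts), dtype=int)
        seg[0::2], seg[1::2] = starts, ends
        if seg[-1] == values.size:  # reduceat indices must be < len(values)
            seg = seg[:-1]
        sums = np.add.reduceat(values, seg)[0::2]
        sumsq = np.add.reduceat(values**2, seg)[0::2]
        mins = np.minimum.reduceat(values, seg)[0::2]
        maxs = np.maximum.reduceat(values, seg)[0::2]
        means = sums / lens
        # population sd per bout: a single-frame bout contributes 0
        var = np.maximum(0.0, sumsq / lens - means**2)
        out["active_bout_length_s"] = float(np.mean(lens / fps))
        out["active_bout_mean"] = float(np.mean(means))
        out["active_bout_std"] = float(np.mean(np.sqrt(var)))
        out["active_bout_total"] = float(np.mean(sums))
        out["active_bout_min"] = float(np.mean(mins))
        out["active_bout_max"] = float(np.mean(maxs))
    else:
        for name in _ACTIVE_ONLY:
            out[name] = float("nan")

    if inact:
        ilens = np.array([e - s for s, e in inact], dtype=float)
        out["inactive_bout_length_s"] = float(np.mean(ilens / fps))
    else:
        out["inactive_bout_length_s"] = float("nan")
    return {name: out[name] for name in PARAMETERS}


def larva_parameters(
    dataset: TrackingDataset,
    epochs: Sequence[Epoch] | None = None,
    activity_floor: float = 0.0,
) -> pd.DataFrame:
    """Per-larva 18-measure parameter table (day and night averages).

    Each of the nine parameters is computed per epoch, then averaged across
    the day epochs and across the night epochs (epochs where a measure is
    missing are skipped for that measure). Returns a DataFrame indexed by
    well id with the 18 canonical measure columns plus ``group``.
    """
    if epochs is None:
        epochs = segment_epochs(dataset, use="full_epochs_only")
    day_epochs = [e for e in epochs if e.label == "day"]
    night_epochs = [e for e in epochs if e.label == "night"]
    if not day_epochs or not night_epochs:
        raise ValueError("need at least one day epoch and one night epoch")

    rows = {}
    for well in dataset.wells:
        values = dataset.traces[well].to_numpy()
        row: dict[str, float] = {}
        for label, eps in (("day", day_epochs), ("night", night_epochs)):
            per_epoch = [
                epoch_parameters(
                    segment_bouts(values, (e.start, e.end), activity_floor, fps=dataset.fps)
                )
                for e in eps
            ]
            for p in PARAMETERS:
                vals = np.array([ep[p] for ep in per_epoch])
                with np.errstate(all="ignore"):
                    row[f"{label}_{p}"] = float(np.nanmean(vals)) if not np.all(np.isnan(vals)) else float("nan")
        rows[well] = row
    table = pd.DataFrame.from_dict(rows, orient="index").loc[:, list(MEASURES)]
    table["group"] = dataset.groups.loc[table.index].to_numpy()
    table.index.name = "larva_id"
    return table


class BoutParameterExtractor:
    """Stateless transformer from a :class:`TrackingDataset` to the
    per-larva 18-measure parameter table.

    sklearn-compatible (``fit`` is a no-op); useful to head a pipeline that
    continues with :class:`~larvaprint.fingerprints.FingerprintScaler`.
    """

    def __init__(self, activity_floor: float = 0.0, use: str = "full_epochs_only"):
        self.activity_floor = activity_floor
        self.use = use

    def get_params(self, deep: bool = True) -> dict:
        return {"activity_floor": self.activity_floor, "use": self.use}

    def set_params(self, **params) -> "BoutParameterExtractor":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: TrackingDataset, y=None) -> "BoutParameterExtractor":
        return self

    def transform(self, X: TrackingDataset) -> pd.DataFrame:
        epochs = segment_epochs(X, use=self.use)
        return larva_parameters(X, epochs, activity_floor=self.activity_floor)

    def fit_transform(self, X: TrackingDataset, y=None) -> pd.DataFrame:
        return self.fit(X, y).transform(X)
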