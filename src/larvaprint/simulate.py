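"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators:

* :func:`simulate_plate` — Δ-pixel locomotor traces as an alternating
  renewal process: exponential inactive/active bout durations whose means
  depend on the day/night epoch and the well's group, and gamma-distributed
  per-frame Δ-pixel amplitudes within active bouts. Inactive frames are
  exactly 0. Group effects enter as multiplicative factors on the epoch
  amplitude and on the bout initiation rate, so the nine behavioral
  parameters respond in an analytically predictable direction.
* :func:`simulate_library` — a conditions × measures matrix of
  standard-normal Z-scores emulating a psychoactive-compound fingerprint
  library, optionally with one planted row that mimics a given query
  fingerprint up to additive Gaussian noise.
* :func:`simulate_peak_matrix` — a peaks × cells negative-binomial
  intensity matrix over two cell conditions with a recorded set of planted
  differential peaks whose second-condition mean is shifted by a
  multiplicative effect size.

All generators are bit-reproducible from their seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .bouts import MEASURES
from .pharmacology import FingerprintLibrary
from .peakstats import PeakIntensityMatrix
from .tracking import LightSchedule, TrackingDataset, segment_epochs

__all__ = [
    "GroupEffect",
    "PlateBaseline",
    "PlateSimConfig",
    "PeakSimConfig",
    "simulate_plate",
    "simulate_library",
    "simulate_peak_matrix",
    "write_ground_truth",
]


@dataclass(frozen=True)
class GroupEffect:
    """Multiplicative effects of one group, relative to baseline.

    Amplitude factors scale the mean Δ-pixel value of active frames;
    bout-rate factors scale the rate of active-bout initiation (i.e.
    divide the mean inactive-bout duration) in the given epoch type.
    """

    day_amplitude_factor: float = 1.0
    night_amplitude_factor: float = 1.0
    day_bout_rate_factor: float = 1.0
    night_bout_rate_factor: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "day_amplitude_factor",
            "night_amplitude_factor",
            "day_bout_rate_factor",
            "night_bout_rate_factor",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def amplitude(self, label: str) -> float:
        return self.day_amplitude_factor if label == "day" else self.night_amplitude_factor

    def bout_rate(self, label: str) -> float:
        return self.day_bout_rate_factor if label == "day" else self.night_bout_rate_factor


@dataclass(frozen=True)
class PlateBaseline:
    """Baseline bout process shared by all groups.

    Mean inactive-bout durations are per epoch type (larvae pause longer at
    night); the active-bout mean and the amplitude scale are common.
    Defaults describe 1 Hz-binned larval locomotor data: frequent short
    movement bouts by day, sparser ones by night, mean active-frame
    amplitude of ~10 Δ-pixel units.
    """

    mean_inactive_bout: dict[str, float] = field(
        default_factory=lambda: {"day": 3.0, "night": 12.0}
    )
    mean_active_bout: float = 2.0
    amplitude_scale: float = 10.0

    def __post_init__(self) -> None:
        if set(self.mean_inactive_bout) != {"day", "night"}:
            raise ValueError("mean_inactive_bout needs 'day' and 'night' entries")
        if any(v <= 0 for v in self.mean_inactive_bout.values()):
            raise ValueError("mean_inactive_bout values must be positive")
        if self.mean_active_bout <= 0 or self.amplitude_scale <= 0:
            raise ValueError("mean_active_bout and amplitude_scale must be positive")


@dataclass(frozen=True)
class PlateSimConfig:
    """Configuration of a simulated tracking plate."""

    n_wells_per_group: int = 48
    group_effects: dict[str, GroupEffect] = field(
        default_factory=lambda: {"wt": GroupEffect(), "mut": GroupEffect()}
    )
    fps: float = 1.0
    duration_hours: float = 48.0
    schedule: LightSchedule = field(default_factory=LightSchedule)
    baseline: PlateBaseline = field(default_factory=PlateBaseline)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_wells_per_group < 1:
            raise ValueError("n_wells_per_group must be positive")
        if not self.group_effects:
            raise ValueError("need at least one group")
        if self.fps <= 0 or self.duration_hours <= 0:
            raise ValueError("fps and duration_hours must be positive")
        if self.duration_hours < 24.0:
            raise ValueError(
                "duration must cover at least one full day and one full night"
            )


_AMPLITUDE_SHAPE = 2.0  # gamma shape of per-frame Δ-pixel amplitudes


def simulate_plate(config: PlateSimConfig) -> TrackingDataset:
    """Simulate a plate of Δ-pixel traces as an alternating renewal process.

    Each well alternates inactive/active bouts with exponential durations
    (inactive mean = baseline per-epoch mean / group bout-rate factor);
    active frames draw gamma(shape 2) amplitudes with mean
    amplitude_scale × group epoch amplitude factor. Bouts are truncated at
    epoch boundaries; each epoch restarts in the inactive state.
    """
    n_frames = int(round(config.fps * config.duration_hours * 3600.0))
    # reuse the epoch segmentation machinery to place day/night boundaries
    probe = TrackingDataset(
        traces=pd.DataFrame({"_": np.zeros(n_frames)}),
        groups=pd.Series({"_": "_"}),
        fps=config.fps,
        schedule=config.schedule,
        start_zt=0.0,
    )
    epochs = segment_epochs(probe, use="all")

    ss = np.random.SeedSequence(config.seed)
    columns: dict[str, np.ndarray] = {}
    groups: dict[str, str] = {}
    children = ss.spawn(len(config.group_effects) * config.n_wells_per_group)
    ci = 0
    for group in config.group_effects:
        effect = config.group_effects[group]
        for w in range(config.n_wells_per_group):
            rng = np.random.default_rng(children[ci])
            ci += 1
            well = f"{group}_{w + 1:03d}"
            values = np.zeros(n_frames)
            for ep in epochs:
                _fill_epoch(values, ep, effect, config, rng)
            columns[well] = values
            groups[well] = group
    return TrackingDataset(
        traces=pd.DataFrame(columns),
        groups=pd.Series(groups),
        fps=config.fps,
        schedule=config.schedule,
        start_zt=0.0,
    )


def _fill_epoch(values, epoch, effect: GroupEffect, config: PlateSimConfig, rng) -> None:
    base = config.baseline
    mean_inactive = base.mean_inactive_bout[epoch.label] / effect.bout_rate(epoch.label)
    mean_active = base.mean_active_bout
    amp_mean = base.amplitude_scale * effect.amplitude(epoch.label)
    frame = epoch.start
    active = False  # epochs start with a pause
    while frame < epoch.end:
        mean_s = mean_active if active else mean_inactive
        n = max(1, int(round(rng.exponential(mean_s) * config.fps)))
        n = min(n, epoch.end - frame)
        if active:
            values[frame : frame + n] = rng.gamma(
                _AMPLITUDE_SHAPE, amp_mean / _AMPLITUDE_SHAPE, size=n
            )
        frame += n
        active = not active


def simulate_library(
    n_conditions: int,
    measures: Sequence[str] = MEASURES,
    mimic_of: pd.Series | None = None,
    mimic_noise: float = 0.0,
    seed: int = 0,
    mimic_name: str = "mimic",
) -> FingerprintLibrary:
    """Simulate a fingerprint library of standard-normal Z-scores.

    When ``mimic_of`` is given, one condition (named ``mimic_name``) is
    planted as the query plus i.i.d. Gaussian noise of scale
    ``mimic_noise``; its annotation reads ``"planted mimic"``.
    """
    if n_conditions < 1:
        raise ValueError("n_conditions must be positive")
    if len(measures) == 0:
        raise ValueError("measures must be non-empty")
    if mimic_noise < 0:
        raise ValueError("mimic_noise must be non-negative")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_conditions, len(measures)))
    names = [f"cond_{i:04d}" for i in range(n_conditions)]
    annotations = pd.Series("random", index=names)
    if mimic_of is not None:
        mimic = mimic_of.reindex(measures)
        if mimic.isna().any():
            raise ValueError(
                "mimic_of does not cover the library measure set: "
                f"missing {list(mimic.index[mimic.isna()])[:3]}"
            )
        slot = n_conditions - 1
        z[slot] = mimic.to_numpy(float) + mimic_noise * rng.standard_normal(len(measures))
        names[slot] = mimic_name
        annotations = pd.Series("random", index=names)
        annotations[mimic_name] = "planted mimic"
    lib = pd.DataFrame(z, index=names, columns=list(measures))
    lib.index.name = "condition"
    return FingerprintLibrary(z=lib, annotations=annotations)


@dataclass(frozen=True)
class PeakSimConfig:
    """Configuration of a simulated two-condition peak-intensity matrix."""

    n_peaks: int = 200
    n_cells: dict[str, int] = field(default_factory=lambda: {"wt": 50, "mut": 50})
    fraction_differential: float = 0.0
    effect_size: float = 4.0
    dispersion: float = 2.0
    base_mean: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_peaks < 1:
            raise ValueError("n_peaks must be positive")
        if len(self.n_cells) != 2:
            raise ValueError("exactly two conditions are required")
        if any(n < 2 for n in self.n_cells.values()):
            raise ValueError("every condition needs >= 2 cells")
        if not (0.0 <= self.fraction_differential <= 1.0):
            raise ValueError("fraction_differential must lie in [0, 1]")
        if self.effect_size <= 0 or self.dispersion <= 0 or self.base_mean <= 0:
            raise ValueError("effect_size, dispersion and base_mean must be positive")

    @property
    def condition_b(self) -> str:
        """The condition receiving the planted effect (second key)."""
        return list(self.n_cells)[1]


def simulate_peak_matrix(config: PeakSimConfig) -> PeakIntensityMatrix:
    """Simulate negative-binomial peak intensities with planted effects.

    Per-peak baseline means are log-normal around ``base_mean``; counts are
    NB with shape ``dispersion`` (variance μ + μ²/dispersion). A random
    subset of round(fraction_differential × n_peaks) peaks has the
    second condition's mean multiplied by ``effect_size``; their ids are
    recorded on the returned matrix as ``planted_peaks``.
    """
    rng = np.random.default_rng(config.seed)
    peaks = [f"peak_{i:05d}" for i in range(config.n_peaks)]
    (lab_a, n_a), (lab_b, n_b) = config.n_cells.items()
    cells = [f"{lab_a}_cell_{i:04d}" for i in range(n_a)] + [
        f"{lab_b}_cell_{i:04d}" for i in range(n_b)
    ]
    condition = pd.Series([lab_a] * n_a + [lab_b] * n_b, index=cells)

    mu = rng.lognormal(mean=math.log(config.base_mean), sigma=0.5, size=config.n_peaks)
    n_diff = int(round(config.fraction_differential * config.n_peaks))
    planted_idx = np.sort(rng.choice(config.n_peaks, size=n_diff, replace=False))

    mu_b = mu.copy()
    mu_b[planted_idx] *= config.effect_size
    r = config.dispersion

    def nb(mean_vec: np.ndarray, n_cols: int) -> np.ndarray:
        p = r / (r + mean_vec)
        return rng.negative_binomial(r, p[:, None], size=(config.n_peaks, n_cols))

    mat = np.concatenate([nb(mu, n_a), nb(mu_b, n_b)], axis=1).astype(float)
    intensity = pd.DataFrame(mat, index=peaks, columns=cells)
    intensity.index.name = "peak"
    return PeakIntensityMatrix(
        intensity=intensity,
        condition=condition,
        planted_peaks=tuple(peaks[i] for i in planted_idx),
    )


def write_ground_truth(path: str | Path, *, seed: int,
                       planted_indices: Sequence[str] | None = None,
                       group_effects: dict[str, GroupEffect] | None = None) -> None:
    """Write the simulation's ground-truth sidecar JSON."""
    doc: dict = {"seed": int(seed)}
    if planted_indices is not None:
        doc["planted_indices"] = list(planted_indices)
    if group_effects is not None:
        doc["group_effects"] = {
            g: {
                "day_amplitude_factor": e.day_amplitude_factor,
                "night_amplitude_factor": e.night_amplitude_factor,
                "day_bout_rate_factor": e.day_bout_rate_factor,
                "night_bout_rate_factor": e.night_bout_rate_factor,
            }
            for g, e in group_effects.items()
        }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
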