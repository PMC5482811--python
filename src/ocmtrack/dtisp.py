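"""Diversified time interval scanning protocol (DTIsp).

Speckle in coherent imaging of live cells decorrelates on several
timescales: almost not at all between B-scan repeats milliseconds apart,
partially over the seconds of one volume, and almost fully between volumes
tens of seconds apart (cytoplasmic motion reshuffles the scatterers).  The
DTIsp therefore revisits every sample position after milliseconds, seconds
and tens of seconds, and averages the resulting looks: N effectively
independent looks reduce the speckle contrast (sigma/mu of intensity) from
1 to 1/sqrt(N).

This module encodes the protocol itself — the raster + revisit schedule,
block temporal averaging (TA), thick-slab spatial compounding
(mean/min/max projection) and linear/logarithmic display mapping.  The
named presets honour the instrument's documented operating points (10 s volumes, 22–120 s
periods, ten-volume averages, 30 s period for zygote kinetics, 120 s for
division imaging); the per-protocol parameter tables are configurable
defaults.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage

from .ascan import axial_pixel_um

US = 1_000_000  # microsecond ticks per second; schedules use integer ticks


@dataclass
class ScanProtocol:
    """Raster geometry plus the revisit schedule of one DTIsp preset."""

    name: str = "custom"
    grid: tuple[int, int] = (128, 128)          # (n_x, n_y) lateral points
    bscan_repeats: int = 1                      # millisecond-scale revisits per Y
    volume_duration_s: float = 10.0
    volume_period_s: float = 30.0               # 22–600 s depending on preset
    ta_window: int = 10                         # volumes per temporal average
    session_duration_s: float = 300.0
    pixel_um: tuple[float, float, float] = (0.9, 0.9, axial_pixel_um())  # dx, dy, dz

    def __post_init__(self) -> None:
        if self.volume_period_s < self.volume_duration_s:
            raise ValueError("volume_period_s must be >= volume_duration_s")
        if self.ta_window < 1 or self.bscan_repeats < 1:
            raise ValueError("counts must be >= 1")
        if min(self.grid) < 1:
            raise ValueError("grid must be >= 1 in each direction")

    def with_overrides(self, **kw) -> "ScanProtocol":
        return replace(self, **kw)


#: Named presets.  Volume periods span the documented 22–120 s range; the
#: zygote-kinetics preset uses the 30 s period of the pronuclear recordings
#: and the division preset the slow 120 s cadence of long sessions.
PROTOCOL_PRESETS: dict[str, ScanProtocol] = {
    "dtisp1": ScanProtocol("dtisp1", volume_period_s=22.0, session_duration_s=220.0),
    "dtisp2": ScanProtocol("dtisp2", volume_period_s=60.0, session_duration_s=600.0),
    "dtisp3": ScanProtocol("dtisp3", volume_period_s=120.0, session_duration_s=1200.0),
    "dtisp4": ScanProtocol(
        "dtisp4", volume_period_s=30.0, session_duration_s=9000.0
    ),  # 2.5 h zygote kinetics
    "dtisp5": ScanProtocol(
        "dtisp5", volume_period_s=120.0, session_duration_s=48600.0
    ),  # 13.5 h division imaging
}


def get_protocol(name: str, **overrides) -> ScanProtocol:
    if name not in PROTOCOL_PRESETS:
        raise ValueError(f"unknown protocol preset {name!r}")
    return PROTOCOL_PRESETS[name].with_overrides(**overrides)


@dataclass
class ScanEvent:
    t_start_us: int
    kind: Literal["bscan", "volume", "timepoint"]
    index: tuple[int, ...]  # volume index (+ y, repeat for bscans)

    @property
    def t_start_s(self) -> float:
        return self.t_start_us / US


@dataclass
class Schedule:
    events: list[ScanEvent] = field(default_factory=list)

    def of_kind(self, kind: str) -> list[ScanEvent]:
        return [e for e in self.events if e.kind == kind]

    @property
    def n_volumes(self) -> int:
        return len(self.of_kind("volume"))


@dataclass
class VolumeImage:
    """One 3D intensity grid, axes (z, y, x), voxel size in um (dz, dy, dx)."""

    grid: np.ndarray
    voxel_um: tuple[float, float, float]
    timestamp_s: float = 0.0
    mapping_state: Literal["amplitude", "linear_display", "log_display"] = "amplitude"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise ValueError("volume grid must be 3D (z, y, x)")
        if self.mapping_state != "log_display" and bool(np.any(self.grid < 0)):
            raise ValueError("intensity volumes must be non-negative")


@dataclass
class CompoundingSpec:
    """Temporal window plus spatial slab-projection parameters."""

    temporal_window: int = 10
    spatial_mode: Literal["mean", "min", "max"] = "min"
    slab_thickness_um: float = 15.0
    axis: Literal["z", "y", "x"] = "z"

    def __post_init__(self) -> None:
        if self.temporal_window < 1:
            raise ValueError("temporal window must be >= 1")
        if self.spatial_mode not in ("mean", "min", "max"):
            raise ValueError(f"unknown spatial mode {self.spatial_mode!r}")


# --- schedule ---------------------------------------------------------------


def build_schedule(protocol: ScanProtocol, include_bscans: bool = False) -> Schedule:
    """Lay out the acquisition events of one session on integer-us ticks.

    One volume starts every ``volume_period_s`` from t=0; the schedule holds
    ``floor(session/period)`` volumes.  Within a volume each of the ``n_y``
    B-scan positions is revisited ``bscan_repeats`` times (emitted only when
    ``include_bscans`` to keep long schedules light).  A ``timepoint`` event
    marks the completion of every block of ``ta_window`` volumes.
    """
    period_us = round(protocol.volume_period_s * US)
    session_us = round(protocol.session_duration_s * US)
    duration_us = round(protocol.volume_duration_s * US)
    n_volumes = session_us // period_us
    events: list[ScanEvent] = []
    if n_volumes == 0:
        warnings.warn("session shorter than one volume period: empty schedule")
        return Schedule(events)
    n_y = protocol.grid[1]
    line_us = duration_us // (n_y * protocol.bscan_repeats)
    for v in range(n_volumes):
        t_vol = v * period_us
        events.append(ScanEvent(t_vol, "volume", (v,)))
        if include_bscans:
            for y in range(n_y):
                for r in range(protocol.bscan_repeats):
                    t = t_vol + (y * protocol.bscan_repeats + r) * line_us
                    events.append(ScanEvent(t, "bscan", (v, y, r)))
    for block in range(n_volumes // protocol.ta_window):
        last = (block + 1) * protocol.ta_window - 1
        events.append(ScanEvent(last * period_us + duration_us, "timepoint", (block,)))
    return Schedule(events)


# --- temporal averaging -----------------------------------------------------


def temporal_average(volumes: Sequence[VolumeImage], window: int) -> list[VolumeImage]:
    """Voxel-wise mean over trailing, non-overlapping blocks of ``window``.

    Each output volume carries the mean timestamp of its block; a trailing
    partial block is dropped.
    """
    if len(volumes) < window:
        raise ValueError("need at least one full block of volumes")
    shape = volumes[0].grid.shape
    voxel = volumes[0].voxel_um
    out: list[VolumeImage] = []
    for start in range(0, len(volumes) - window + 1, window):
        block = volumes[start : start + window]
        for v in block:
            if v.grid.shape != shape:
                raise ValueError("volume shape mismatch within averaging block")
            if v.mapping_state != "amplitude":
                raise ValueError("temporal averaging operates on unmapped intensities")
        mean = np.mean([v.grid for v in block], axis=0)
        t = float(np.mean([v.timestamp_s for v in block]))
        out.append(VolumeImage(mean.astype(volumes[0].grid.dtype, copy=False), voxel, t))
    return out


# --- spatial compounding ----------------------------------------------------

_AXIS_INDEX = {"z": 0, "y": 1, "x": 2}
_REDUCERS = {
    "mean": ndimage.uniform_filter1d,
    "min": ndimage.minimum_filter1d,
    "max": ndimage.maximum_filter1d,
}


def slab_size_voxels(slab_thickness_um: float, voxel_um: float) -> int:
    """Number of slices in a slab (e.g. 15 um at dz=0.879 um -> 17)."""
    return max(2, round(slab_thickness_um / voxel_um))


def spatial_compound(volume: VolumeImage, spec: CompoundingSpec) -> VolumeImage:
    """Sliding-slab projection along one axis, edge-clamped, same shape."""
    axis = _AXIS_INDEX[spec.axis]
    voxel = volume.voxel_um[axis]
    size = slab_size_voxels(spec.slab_thickness_um, voxel)
    if spec.slab_thickness_um <= voxel:
        raise ValueError("slab thinner than one voxel along the projection axis")
    reducer = _REDUCERS[spec.spatial_mode]
    out = reducer(volume.grid.astype(float), size=size, axis=axis, mode="nearest")
    return VolumeImage(out, volume.voxel_um, volume.timestamp_s, volume.mapping_state)


# --- display mapping --------------------------------------------------------


def map_intensity(
    volume: VolumeImage,
    mode: Literal["linear", "log"] = "linear",
    floor_db: float = -40.0,
    reference_percentile: float = 99.5,
) -> VolumeImage:
    """Map raw intensities to [0, 1] for display.

    Linear mapping (divide by the high-percentile reference, clip) emphasizes
    cytoplasmic structure; logarithmic mapping (dB relative to the same
    reference, clipped at ``floor_db`` and rescaled) favours the darker
    nuclear interior.  The dB value of an intensity ratio equals 20*log10 of
    the corresponding amplitude ratio.
    """
    if volume.mapping_state != "amplitude":
        raise ValueError("volume already display-mapped")
    grid = volume.grid.astype(float)
    ref = float(np.percentile(grid, reference_percentile))
    if ref <= 0:
        warnings.warn("all-zero volume: display output is zeros")
        return VolumeImage(
            np.zeros_like(grid), volume.voxel_um, volume.timestamp_s,
            "linear_display" if mode == "linear" else "log_display",
        )
    if mode == "linear":
        out = np.clip(grid / ref, 0.0, 1.0)
        state: Literal["linear_display", "log_display"] = "linear_display"
    elif mode == "log":
        if floor_db >= 0:
            raise ValueError("floor_db must be negative")
        with np.errstate(divide="ignore"):
            db = 10.0 * np.log10(grid / ref)
        db = np.clip(db, floor_db, 0.0)
        out = (db - floor_db) / (-floor_db)
        state = "log_display"
    else:
        raise ValueError(f"unknown mapping mode {mode!r}")
    return VolumeImage(out, volume.voxel_um, volume.timestamp_s, state)


def speckle_contrast(values: np.ndarray) -> float:
    """sigma/mu of an intensity sample (1.0 for fully developed speckle)."""
    values = np.asarray(values, dtype=float).ravel()
    mu = values.mean()
    if mu == 0:
        raise ValueError("zero-mean sample has undefined contrast")
    return float(values.std() / mu)
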