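"""Quantitative readouts from tracked objects.

Turns per-frame label volumes into the study's measurements: per-object
volume and centroid trajectories with velocities, inter-pronuclear distance
series (control zygotes approach, microtubule-depolymerized ones do not),
line intensity profiles across nuclei, and the NSN/SN chromatin score built
from the peri-nucleolar ring contrast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .dtisp import VolumeImage
from .segtrack import LabeledObjects, TrackState


@dataclass
class Trajectory:
    """Per-object time series of centroid, volume and velocity."""

    object_tag: str
    samples: pd.DataFrame  # t_s, cz_um, cy_um, cx_um, volume_um3, speed_um_min

    def __post_init__(self) -> None:
        t = self.samples["t_s"].to_numpy()
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("trajectory timestamps must be strictly increasing")

    @property
    def centroids_um(self) -> np.ndarray:
        return self.samples[["cz_um", "cy_um", "cx_um"]].to_numpy()


@dataclass
class IntensityProfile:
    start_um: tuple[float, float, float]
    end_um: tuple[float, float, float]
    positions_um: np.ndarray
    intensities: np.ndarray


@dataclass
class ChromatinScore:
    """Peri-nucleolar ring contrast and the derived NSN/SN class."""

    ring_contrast: float
    mean_nuclear_intensity: float
    chromatin_class: str           # NSN | transition | SN | undefined
    thresholds: tuple[float, float] = (1.1, 1.4)


# --- trajectories -----------------------------------------------------------


def _velocities_um_min(t_s: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Centered finite difference over a 3-sample window, um/min."""
    n = t_s.size
    v = np.zeros(n)
    if n == 1:
        return v
    for i in range(n):
        lo = max(0, i - 1)
        hi = min(n - 1, i + 1)
        dt_min = (t_s[hi] - t_s[lo]) / 60.0
        v[i] = float(np.linalg.norm(centroids[hi] - centroids[lo])) / dt_min
    return v


def measure_objects(track: TrackState, timestamps_s: dict[int, float] | None = None
                    ) -> dict[str, Trajectory]:
    """Trajectories of every tagged object in a track.

    Volume is the exact voxel count times the voxel volume; the centroid is
    the unweighted mask centroid.  ``timestamps_s`` maps frame index to
    acquisition time (defaults to the frame index, i.e. 1 s cadence).
    """
    if not track.frames:
        raise ValueError("empty track")
    tags: dict[str, list] = {}
    for frame in track.frame_indices():
        objs = track.frames[frame]
        voxel_vol = float(np.prod(objs.voxel_um))
        t = float(timestamps_s[frame]) if timestamps_s else float(frame)
        for rec in objs.records:
            if rec.tag is None:
                continue
            tags.setdefault(rec.tag, []).append(
                (t, *rec.centroid_um, rec.voxel_count * voxel_vol)
            )
    out = {}
    for tag, rows in tags.items():
        df = pd.DataFrame(rows, columns=["t_s", "cz_um", "cy_um", "cx_um", "volume_um3"])
        df = df.sort_values("t_s", ignore_index=True)
        df["speed_um_min"] = _velocities_um_min(
            df["t_s"].to_numpy(), df[["cz_um", "cy_um", "cx_um"]].to_numpy()
        )
        out[tag] = Trajectory(tag, df)
    return out


def pairwise_distance_series(traj_a: Trajectory, traj_b: Trajectory) -> pd.DataFrame:
    """Euclidean centroid distance at every shared timepoint."""
    merged = pd.merge(
        traj_a.samples, traj_b.samples, on="t_s", suffixes=("_a", "_b")
    )
    if merged.empty:
        warnings.warn("trajectories share no timepoints: empty distance series")
        return pd.DataFrame(columns=["t_s", "distance_um"])
    delta = (
        merged[["cz_um_a", "cy_um_a", "cx_um_a"]].to_numpy()
        - merged[["cz_um_b", "cy_um_b", "cx_um_b"]].to_numpy()
    )
    return pd.DataFrame(
        {"t_s": merged["t_s"], "distance_um": np.linalg.norm(delta, axis=1)}
    )


# --- intensity profiles -----------------------------------------------------


def line_profile(
    volume: VolumeImage,
    start_um: tuple[float, float, float],
    end_um: tuple[float, float, float],
    step_um: float = 0.3,
) -> IntensityProfile:
    """Trilinear interpolation at uniform sub-voxel steps along a segment."""
    start = np.asarray(start_um, dtype=float)
    end = np.asarray(end_um, dtype=float)
    extent = np.asarray(volume.grid.shape) * np.asarray(volume.voxel_um)
    for p in (start, end):
        if np.any(p < 0) or np.any(p > extent):
            raise ValueError(f"profile endpoint {tuple(p)} outside the volume")
    length = float(np.linalg.norm(end - start))
    n = max(2, int(np.floor(length / step_um)) + 1)
    positions = np.linspace(0.0, length, n)
    points = start[None, :] + (end - start)[None, :] * (positions / length)[:, None]
    voxel_coords = (points / np.asarray(volume.voxel_um)[None, :]) - 0.5
    values = ndimage.map_coordinates(
        volume.grid.astype(float), voxel_coords.T, order=1, mode="nearest"
    )
    return IntensityProfile(tuple(start), tuple(end), positions, values)


def diameter_through_nucleolus(
    nucleus_centroid_um, nucleolus_centroid_um, radius_um
) -> tuple[tuple[float, float, float], tuple[float, float, float]]:
    """Default profile line: the nuclear diameter through a nucleolus."""
    c = np.asarray(nucleus_centroid_um, dtype=float)
    d = np.asarray(nucleolus_centroid_um, dtype=float) - c
    norm = np.linalg.norm(d)
    axis = d / norm if norm > 1e-9 else np.array([0.0, 1.0, 0.0])
    return tuple(c - axis * radius_um), tuple(c + axis * radius_um)


# --- chromatin --------------------------------------------------------------


def _polar_cones(nucleoli: LabeledObjects, pad_vox: int) -> np.ndarray:
    """45-degree cones above/below each nucleolus centroid (specular zone)."""
    cones = np.zeros(nucleoli.label_volume.shape, dtype=bool)
    voxel = np.asarray(nucleoli.voxel_um, dtype=float)
    for rec in nucleoli.records:
        sl = tuple(
            slice(max(0, s.start - pad_vox), min(dim, s.stop + pad_vox))
            for s, dim in zip(rec.bbox, cones.shape)
        )
        center_vox = [rec.centroid_um[i] / voxel[i] - 0.5 for i in range(3)]
        dz = (np.arange(sl[0].start, sl[0].stop) - center_vox[0]) * voxel[0]
        dy = (np.arange(sl[1].start, sl[1].stop) - center_vox[1]) * voxel[1]
        dx = (np.arange(sl[2].start, sl[2].stop) - center_vox[2]) * voxel[2]
        lateral = np.hypot(dy[:, None], dx[None, :])
        cones[sl] |= np.abs(dz)[:, None, None] >= lateral[None, :, :]
    return cones


def classify_chromatin(
    volume: VolumeImage,
    nucleus: LabeledObjects,
    nucleoli: LabeledObjects,
    thresholds: tuple[float, float] = (1.1, 1.4),
    shell_vox: int = 2,
) -> ChromatinScore:
    """Score the chromatin configuration from the peri-nucleolar ring.

    ``ring_contrast`` is the mean intensity of a ``shell_vox``-voxel shell
    around the nucleoli divided by the mean of the remaining nucleoplasm.
    SN oocytes condense chromatin into that ring (high contrast), NSN keep
    it dispersed (contrast near 1 but a brighter nucleus overall).
    """
    nuc_mask = nucleus.mask()
    nucl_mask = nucleoli.mask()
    if not nucl_mask.any():
        warnings.warn("no nucleolus: chromatin score undefined")
        return ChromatinScore(np.nan, float(volume.grid[nuc_mask].mean()),
                              "undefined", thresholds)
    shell = ndimage.binary_dilation(
        nucl_mask, structure=np.ones((3, 3, 3), bool), iterations=shell_vox
    )
    ring = shell & nuc_mask & ~nucl_mask
    # the top/bottom nucleolus border carries a specular reflex (a coherent
    # back-reflection artifact, not chromatin); assess the ring laterally
    ring &= ~_polar_cones(nucleoli, shell_vox + 2)
    rest = nuc_mask & ~shell & ~nucl_mask
    grid = volume.grid.astype(float)
    if not ring.any() or not rest.any():
        return ChromatinScore(np.nan, float(grid[nuc_mask].mean()),
                              "undefined", thresholds)
    contrast = float(grid[ring].mean() / grid[rest].mean())
    lo, hi = thresholds
    cls = "NSN" if contrast < lo else ("SN" if contrast > hi else "transition")
    nucleoplasm = nuc_mask & ~nucl_mask
    return ChromatinScore(contrast, float(grid[nucleoplasm].mean()), cls, thresholds)
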