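"""File formats, run configuration and the chained pipeline.

Volumes travel as OME-TIFF / multi-page TIFF in TZYX order with voxel
sizes in um; raw spectra as HDF5 (``/spectra``, ``/wavelength_nm``); seed
annotations, event logs, scores and manifests as JSON; trajectories,
distance series and profiles as CSV with units in the headers; run
configuration as YAML.  :func:`run_pipeline` chains scenario simulation,
DTIsp averaging, optional slab projection, display mapping, seeded
tracking and quantification, and writes a checksummed manifest so every
run is reproducible from its manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import h5py
import numpy as np
import tifffile
import yaml

from . import __version__
from .ascan import SpectralFrame
from .dtisp import (
    CompoundingSpec,
    ScanProtocol,
    VolumeImage,
    map_intensity,
    spatial_compound,
    temporal_average,
)
from .phantom import make_scenario, simulate_session
from .quantify import measure_objects, pairwise_distance_series
from .segtrack import SeedAnnotation, SegmentationParams, track_sequence

logger = logging.getLogger("ocmtrack")


# --- TIFF volumes -----------------------------------------------------------


def write_volume_series(path, volumes: Sequence[VolumeImage], ome: bool = False) -> None:
    """Write a TZYX multi-page TIFF with voxel-size and timestamp metadata.

    The default (shaped-metadata) form is byte-deterministic, which keeps run
    manifests reproducible; ``ome=True`` exports OME-TIFF instead (standard
    for interchange, but stamped with a fresh UUID on every write).
    """
    path = Path(path)
    data = np.stack([v.grid for v in volumes]).astype(np.float32)
    dz, dy, dx = volumes[0].voxel_um
    if str(path).endswith((".ome.tif", ".ome.tiff")):
        ome = True  # tifffile treats the extension as an OME request anyway
    if ome:
        tifffile.imwrite(
            path,
            data,
            ome=True,
            metadata={
                "axes": "TZYX",
                "PhysicalSizeZ": dz,
                "PhysicalSizeY": dy,
                "PhysicalSizeX": dx,
                "PhysicalSizeZUnit": "µm",
                "PhysicalSizeYUnit": "µm",
                "PhysicalSizeXUnit": "µm",
            },
        )
        return
    tifffile.imwrite(
        path,
        data,
        ome=False,
        metadata={
            "axes": "TZYX",
            "voxel_um": [float(dz), float(dy), float(dx)],
            "timestamps_s": [float(v.timestamp_s) for v in volumes],
        },
    )


def read_volume_series(
    path,
    voxel_um: tuple[float, float, float] | None = None,
    period_s: float | None = None,
) -> list[VolumeImage]:
    """Read a TZYX (or ZYX, single timepoint) TIFF series.

    Voxel sizes come from the OME metadata; explicit ``voxel_um`` overrides
    them (with a warning when both are present).  Timestamps come from the
    embedded description, else from ``period_s``, else default to the frame
    index in seconds.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        axes = series.axes.upper()
        data = series.asarray()
        meta_voxel = None
        timestamps = None
        shaped = tif.shaped_metadata
        if shaped and "voxel_um" in shaped[0]:
            meta_voxel = tuple(float(v) for v in shaped[0]["voxel_um"])
        if shaped and "timestamps_s" in shaped[0]:
            timestamps = shaped[0]["timestamps_s"]
        if meta_voxel is None and tif.ome_metadata:
            import re

            m = {
                k: re.search(rf'{k}="([0-9.eE+-]+)"', tif.ome_metadata)
                for k in ("PhysicalSizeZ", "PhysicalSizeY", "PhysicalSizeX")
            }
            if all(m.values()):
                meta_voxel = tuple(float(m[k].group(1)) for k in
                                   ("PhysicalSizeZ", "PhysicalSizeY", "PhysicalSizeX"))
    if axes == "ZYX" or (data.ndim == 3 and axes in ("QYX", "IYX")):
        data = data[None]
    elif axes not in ("TZYX", "IZYX", "QZYX"):
        if data.ndim == 4:
            raise ValueError(
                f"ambiguous axis order {axes!r}: expected TZYX; pass data in TZYX order"
            )
        raise ValueError(f"expected a TZYX or ZYX stack, got axes {axes!r} "
                         f"(missing Z and/or T)")
    if voxel_um is not None:
        if meta_voxel is not None:
            warnings.warn("voxel size flags override TIFF metadata")
        use_voxel = tuple(voxel_um)
    elif meta_voxel is not None:
        use_voxel = meta_voxel
    else:
        raise ValueError("no voxel-size metadata: pass voxel_um (--dz/--dy/--dx)")
    out = []
    for t in range(data.shape[0]):
        if timestamps is not None and t < len(timestamps):
            ts = float(timestamps[t])
        else:
            ts = t * (period_s if period_s else 1.0)
        out.append(VolumeImage(data[t].astype(np.float32), use_voxel, ts))
    return out


def write_label_series(path, labels: Sequence[np.ndarray],
                       voxel_um: tuple[float, float, float]) -> None:
    vols = [VolumeImage(lbl.astype(np.float32), voxel_um, t) for t, lbl in
            enumerate(labels)]
    write_volume_series(path, vols)


# --- HDF5 raw spectra -------------------------------------------------------


def write_spectra_h5(path, frames: Sequence[SpectralFrame]) -> None:
    """Raw-frame container: /spectra (frames x n_pix), /wavelength_nm."""
    with h5py.File(path, "w") as f:
        f.create_dataset(
            "spectra", data=np.stack([fr.samples for fr in frames]).astype(np.float32)
        )
        f.create_dataset("wavelength_nm", data=frames[0].wavelength_nm)
        f.attrs["line_period_s"] = frames[0].line_period_s
        f.attrs["n_pix"] = frames[0].n_pix


def read_spectra_h5(path) -> list[SpectralFrame]:
    with h5py.File(path, "r") as f:
        spectra = f["spectra"][()]
        wavelength = f["wavelength_nm"][()]
        period = float(f.attrs.get("line_period_s", 1.0 / 140e3))
    return [SpectralFrame(s, wavelength, period) for s in spectra]


# --- seeds, events, scores --------------------------------------------------


def write_seed_json(path, seed: SeedAnnotation) -> None:
    payload = {
        "frame": seed.frame_index,
        "points": [
            {"tag": tag, "z_um": p[0], "y_um": p[1], "x_um": p[2]}
            for tag, p in seed.points_um.items()
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_seed_json(path) -> SeedAnnotation:
    payload = json.loads(Path(path).read_text())
    points = {
        pt["tag"]: (pt["z_um"], pt["y_um"], pt["x_um"]) for pt in payload["points"]
    }
    return SeedAnnotation(payload["frame"], points)


# --- run configuration ------------------------------------------------------


@dataclass
class RunConfig:
    """Everything one pipeline run needs, loadable from YAML."""

    scenario: str = "fig5_control"
    scenario_overrides: dict[str, Any] = field(default_factory=dict)
    protocol: dict[str, Any] = field(default_factory=dict)
    projection: dict[str, Any] | None = None     # {mode, slab_um, axis}
    mapping_mode: str = "linear"
    segmentation: dict[str, Any] = field(default_factory=dict)
    input_volumes: str | None = None             # external TIFF instead of phantom
    seed_json: str | None = None
    output_dir: str = "ocmtrack_run"
    rng_seed: int = 1
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**payload)

    def to_dict(self) -> dict[str, Any]:
        from dataclasses import asdict

        return asdict(self)


@dataclass
class DatasetManifest:
    files: dict[str, str]            # relative path -> sha256
    config: dict[str, Any]
    software_version: str = __version__

    def write(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {"software_version": self.software_version,
                 "config": self.config, "files": self.files},
                indent=2, default=str,
            )
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


# --- pipeline ---------------------------------------------------------------


def run_pipeline(config: RunConfig) -> DatasetManifest:
    """Simulation -> averaging -> (projection) -> mapping -> tracking -> CSVs.

    Deterministic for a fixed ``rng_seed``.  With ``input_volumes`` set, the
    phantom stage is replaced by reading an external TZYX TIFF, in which
    case an explicit seed-annotation JSON is required.
    """
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    scenario_overrides = dict(config.scenario_overrides)
    scenario_overrides.setdefault("rng_seed", config.rng_seed)
    protocol = ScanProtocol(**{"name": "run", **config.protocol})

    if config.input_volumes:
        if not config.seed_json:
            raise RuntimeError(
                "stage ingest: external volumes need a seed annotation (--seed-json)"
            )
        averaged = read_volume_series(config.input_volumes)
        seed = read_seed_json(config.seed_json)
        truths = None
        logger.info("ingested %d external volumes", len(averaged))
    else:
        phantom = make_scenario(config.scenario, **_coerce_overrides(scenario_overrides))
        averaged, truths = simulate_session(phantom, protocol)
        if not averaged:
            raise RuntimeError("stage simulate: schedule produced no volumes")
        seed = _seed_from_truth(truths[0], frame_index=0)
        logger.info("simulated %d averaged timepoints", len(averaged))

    vol_path = out_dir / "volumes.tif"
    write_volume_series(vol_path, averaged)
    files["volumes.tif"] = vol_path

    if config.projection:
        spec = CompoundingSpec(
            temporal_window=1,
            spatial_mode=config.projection.get("mode", "min"),
            slab_thickness_um=config.projection.get("slab_um", 15.0),
            axis=config.projection.get("axis", "z"),
        )
        averaged = [spatial_compound(v, spec) for v in averaged]

    display = [map_intensity(v, mode=config.mapping_mode) for v in averaged]

    params = SegmentationParams(**config.segmentation)
    track = track_sequence(display, seed, params)

    events_path = out_dir / "events.jsonl"
    with events_path.open("w") as f:
        for frame in track.frame_indices():
            ev = track.events[frame]
            f.write(json.dumps({"frame": frame, "merged": ev.merged,
                                "divided": ev.divided,
                                "disappeared": ev.disappeared}) + "\n")
    files["events.jsonl"] = events_path

    timestamps = {i: v.timestamp_s for i, v in enumerate(averaged)}
    trajectories = measure_objects(track, timestamps)
    traj_path = out_dir / "trajectories.csv"
    rows = []
    for tag, traj in sorted(trajectories.items()):
        df = traj.samples.copy()
        df.insert(0, "tag", tag)
        rows.append(df)
    import pandas as pd

    pd.concat(rows, ignore_index=True).to_csv(traj_path, index=False)
    files["trajectories.csv"] = traj_path

    tags = sorted(trajectories)
    if len(tags) == 2:
        dist = pairwise_distance_series(trajectories[tags[0]], trajectories[tags[1]])
        dist_path = out_dir / "distance.csv"
        dist.to_csv(dist_path, index=False)
        files["distance.csv"] = dist_path

    seed_path = out_dir / "seed.json"
    write_seed_json(seed_path, seed)
    files["seed.json"] = seed_path

    manifest = DatasetManifest(
        files={name: _sha256(p) for name, p in files.items()},
        config=config.to_dict(),
    )
    manifest.write(out_dir / "manifest.json")
    return manifest


def _coerce_overrides(overrides: dict[str, Any]) -> dict[str, Any]:
    out = dict(overrides)
    for key in ("grid_shape", "voxel_um"):
        if key in out and isinstance(out[key], list):
            out[key] = tuple(out[key])
    return out


def _seed_from_truth(truth, frame_index: int = 0) -> SeedAnnotation:
    """Expert-seed surrogate: true nuclear centroids of the first timepoint."""
    nuclear = truth.objects[truth.objects["class"].isin(["pronucleus", "nucleus"])]
    points = {}
    for _, row in nuclear.iterrows():
        points[row["tag"]] = (row["cz_um"], row["cy_um"], row["cx_um"])
    if not points:
        raise RuntimeError("stage seed: no nuclear objects in ground truth")
    return SeedAnnotation(frame_index, points)
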