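"""Seed-initialized segmentation and tracking of zygote structures.

A human expert marks the male and female pronuclei once, in a single frame
of the 4D recording; from that frame the algorithm traces the structures
forward and backward in time.  Each frame is processed the same way:

1. cell-body extraction — per-slice Otsu thresholding with a locally
   adjusted (z-smoothed) threshold, 2D hole filling, 3D morphological
   opening, largest connected component, 3D cavity filling (cavities that
   contain a previous frame's pronucleus are filled even when they open to
   the boundary, the "pronucleus close to the membrane" case);
2. nuclear-object detection — inside the cell mask, Otsu thresholding of
   the inverted intensity with a dynamically tuned scale factor until the
   dark class yields 1–4 sufficiently large candidates, each candidate
   approximated by its half-scale inertia ellipsoid, and those ellipsoids
   used as markers of a seeded watershed; objects absent from the previous
   frame are rejected;
3. merge assessment with two-threshold (3-class) Otsu, division detection
   from sudden principal-axis-ratio changes or object splits;
4. nucleolus segmentation inside each nucleus by adaptive (local-mean)
   thresholding plus morphological closing.

Objects of interest are dark on the bright speckled cytoplasm, so all
detectors operate on inverted intensity within the cell mask.  3D
connectivity is 26-neighborhood, 2D is 8-neighborhood.  Every free
constant lives in :class:`SegmentationParams`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage
from skimage.morphology import ball
from skimage.segmentation import watershed

from .dtisp import VolumeImage

_STRUCT_3D = np.ones((3, 3, 3), dtype=bool)   # 26-connectivity
_STRUCT_2D = np.ones((3, 3), dtype=bool)      # 8-connectivity

N_HIST_BINS = 256


# --- domain types -----------------------------------------------------------


@dataclass
class SeedAnnotation:
    """Expert-marked pronucleus locations in one frame."""

    frame_index: int
    points_um: dict[str, tuple[float, float, float]]  # tag -> (z, y, x) um

    def __post_init__(self) -> None:
        pts = list(self.points_um.values())
        if len(pts) != len({tuple(p) for p in pts}):
            raise ValueError("seed points must be distinct")


@dataclass
class SegmentationParams:
    """Every free constant of the segmentation/tracking chain."""

    otsu_local_factor: float = 1.0       # per-z threshold multiplier
    z_threshold_smoothing: int = 5       # median window across slices
    opening_radius_vox: int = 2
    smoothing_sigma_vox: float = 1.0     # pre-filter against residual speckle
    dynamic_otsu_bounds: tuple[float, float] = (0.7, 1.3)
    dynamic_otsu_step: float = 0.05
    min_object_vox: int = 200
    max_candidates: int = 4
    max_candidate_frac: float = 0.2      # of the cell volume; a larger dark
    # component means the threshold crossed into the cytoplasm itself
    min_object_contrast: float = 2.0     # nuclei are uniformly grey, at least
    # this factor darker than the bright cytoplasm class; rejects dark-tail
    # speckle blobs in homogeneous cytoplasm
    cell_margin_vox: int = 3             # erosion of the cell mask before the
    # dark-object search: boundary voxels darkened by partial-volume mixing
    # with the medium would otherwise mimic nuclear candidates
    overlap_accept_iou: float = 0.05
    overlap_accept_shift_um: float = 10.0
    shape_change_ratio: float = 1.5      # division trigger on axis-ratio jump
    nucleolus_window_vox: int = 7
    nucleolus_offset: float = 0.05       # in units of the mean nuclear intensity
    nucleolus_max_frac: float = 0.35     # nucleoli are near-black: well below
    # the mean nuclear intensity (also keeps N-look speckle dips out)
    nucleolus_margin_vox: int = 2        # stay clear of the bright nuclear rim
    nucleolus_min_vox: int = 30
    closing_radius_vox: int = 1

    def __post_init__(self) -> None:
        lo, hi = self.dynamic_otsu_bounds
        if not (0 < lo <= hi):
            raise ValueError("dynamic_otsu_bounds must be ordered and positive")
        for name in ("otsu_local_factor", "z_threshold_smoothing",
                     "opening_radius_vox", "min_object_vox",
                     "shape_change_ratio", "nucleolus_window_vox",
                     "closing_radius_vox"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ObjectRecord:
    id: int
    cls: Literal["cell_body", "pronucleus", "nucleus", "spindle", "nucleolus"]
    tag: str | None
    voxel_count: int
    centroid_um: tuple[float, float, float]
    bbox: tuple[slice, slice, slice]
    frame: int


@dataclass
class LabeledObjects:
    """A label volume plus one record per object."""

    label_volume: np.ndarray
    records: list[ObjectRecord]
    voxel_um: tuple[float, float, float]
    frame: int = 0
    disappeared: bool = False    # no candidate at any threshold (e.g. NEBD)

    def mask(self, object_id: int | None = None) -> np.ndarray:
        if object_id is None:
            return self.label_volume > 0
        return self.label_volume == object_id

    @property
    def n_objects(self) -> int:
        return len(self.records)

    def by_tag(self, tag: str) -> ObjectRecord:
        for rec in self.records:
            if rec.tag == tag:
                return rec
        raise KeyError(tag)


@dataclass
class FrameEvents:
    merged: bool = False
    divided: bool = False
    disappeared: bool = False


@dataclass
class TrackState:
    """Per-frame objects, adjacent-frame links and event flags."""

    frames: dict[int, LabeledObjects] = field(default_factory=dict)
    links: list[tuple[int, int, int, int]] = field(default_factory=list)
    # (frame_t, id_t, frame_t1, id_t1); frame_t1 == frame_t + 1
    events: dict[int, FrameEvents] = field(default_factory=dict)

    def add_link(self, frame_t: int, id_t: int, frame_t1: int, id_t1: int) -> None:
        if frame_t1 != frame_t + 1:
            raise ValueError("links must connect adjacent frames")
        self.links.append((frame_t, id_t, frame_t1, id_t1))

    def frame_indices(self) -> list[int]:
        return sorted(self.frames)


# --- Otsu thresholding ------------------------------------------------------


def otsu_threshold(histogram: np.ndarray) -> int:
    """Bin index maximizing between-class variance; ties go to the lowest bin.

    The returned threshold ``t`` separates bins ``<= t`` from bins ``> t``.
    """
    hist = np.asarray(histogram, dtype=np.float64)
    if np.count_nonzero(hist) < 2:
        raise ValueError("histogram needs at least two nonempty bins")
    n = hist.size
    bins = np.arange(n, dtype=np.float64)
    w0 = np.cumsum(hist)[:-1]
    w1 = hist.sum() - w0
    s0 = np.cumsum(hist * bins)[:-1]
    total = (hist * bins).sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = s0 / w0
        mu1 = (total - s0) / w1
        var_between = w0 * w1 * (mu0 - mu1) ** 2
    var_between[(w0 == 0) | (w1 == 0)] = -np.inf
    return int(np.argmax(var_between))


def otsu_threshold_two(histogram: np.ndarray) -> tuple[int, int]:
    """Two thresholds ``(t1, t2)`` maximizing 3-class between-class variance.

    Classes are bins ``<= t1``, ``t1 < bins <= t2`` and ``> t2``; ties break
    toward the lowest (t1, t2) pair.
    """
    hist = np.asarray(histogram, dtype=np.float64)
    if np.count_nonzero(hist) < 3:
        raise ValueError("histogram needs at least three nonempty bins")
    n = hist.size
    bins = np.arange(n, dtype=np.float64)
    cw = np.concatenate([[0.0], np.cumsum(hist)])          # cw[i] = sum(hist[:i])
    cs = np.concatenate([[0.0], np.cumsum(hist * bins)])
    best = -np.inf
    best_pair = (0, 1)
    for t1 in range(n - 2):
        w0 = cw[t1 + 1]
        if w0 == 0:
            continue
        m0 = cs[t1 + 1] ** 2 / w0
        t2 = np.arange(t1 + 1, n - 1)
        w1 = cw[t2 + 1] - cw[t1 + 1]
        w2 = cw[n] - cw[t2 + 1]
        valid = (w1 > 0) & (w2 > 0)
        if not np.any(valid):
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            crit = (
                m0
                + (cs[t2 + 1] - cs[t1 + 1]) ** 2 / w1
                + (cs[n] - cs[t2 + 1]) ** 2 / w2
            )
        crit[~valid] = -np.inf
        j = int(np.argmax(crit))
        if crit[j] > best:
            best = crit[j]
            best_pair = (t1, int(t2[j]))
    return best_pair


def _histogram(values: np.ndarray, vmin: float, vmax: float) -> np.ndarray:
    hist, _ = np.histogram(values, bins=N_HIST_BINS, range=(vmin, vmax))
    return hist


def _threshold_value(values: np.ndarray, vmin: float, vmax: float) -> float:
    """Otsu threshold of a value sample, returned on the intensity scale."""
    t = otsu_threshold(_histogram(values, vmin, vmax))
    edges = np.linspace(vmin, vmax, N_HIST_BINS + 1)
    return float(edges[t + 1])  # upper edge of the last below-class bin


def _log_threshold_value(values: np.ndarray) -> float:
    """Otsu threshold on the log-intensity histogram, on the intensity scale.

    Dark nuclear objects occupy only a few percent of the cell volume, so on
    a linear histogram Otsu splits the broad bright cytoplasm mode instead;
    log intensities make the two modes comparably wide and the valley between
    them the dominant split.  Scaling all intensities shifts the log
    histogram, so the returned threshold scales with the data.
    """
    positive = values[values > 0]
    lv = np.log10(positive)
    t = otsu_threshold(_histogram(lv, float(lv.min()), float(lv.max())))
    edges = np.linspace(float(lv.min()), float(lv.max()), N_HIST_BINS + 1)
    return float(10.0 ** edges[t + 1])


# --- cell body --------------------------------------------------------------


def extract_cell_body(
    volume: VolumeImage,
    params: SegmentationParams | None = None,
    prior: Sequence[tuple[float, float, float]] | None = None,
    frame: int = 0,
) -> LabeledObjects:
    """Extract the single cell body from a display-linear volume.

    ``prior`` gives pronucleus locations (um) from the adjacent processed
    frame; cavities containing them are filled even when open to the mask
    boundary.
    """
    params = params or SegmentationParams()
    grid = volume.grid.astype(np.float32)
    if params.smoothing_sigma_vox > 0:
        grid = ndimage.gaussian_filter(grid, params.smoothing_sigma_vox)
    vmin, vmax = float(grid.min()), float(grid.max())
    if vmax <= vmin:
        raise ValueError("no cell: volume has no dynamic range")
    nz = grid.shape[0]
    thresholds = np.empty(nz)
    for z in range(nz):
        sl = grid[z]
        try:
            thresholds[z] = (
                _threshold_value(sl.ravel(), vmin, vmax) * params.otsu_local_factor
            )
        except ValueError:  # flat slice (e.g. pure medium): no foreground
            thresholds[z] = np.inf
    finite = np.isfinite(thresholds)
    if not finite.any():
        raise ValueError("no cell: every slice is flat")
    thresholds[~finite] = np.nanmax(thresholds[finite])
    thresholds = ndimage.median_filter(
        thresholds, size=params.z_threshold_smoothing, mode="nearest"
    )
    mask = grid > thresholds[:, None, None]
    for z in range(nz):  # 2D cavity filling, slice by slice
        mask[z] = ndimage.binary_fill_holes(mask[z], structure=_STRUCT_2D)
    mask = ndimage.binary_opening(mask, structure=ball(params.opening_radius_vox))
    labeled, n = ndimage.label(mask, structure=_STRUCT_3D)
    if n == 0:
        raise ValueError("no cell: empty foreground after opening")
    sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, np.arange(1, n + 1))
    cell = labeled == (1 + int(np.argmax(sizes)))
    cell = ndimage.binary_fill_holes(cell, structure=_STRUCT_3D)
    if prior is not None:
        cell = _fill_prior_cavities(cell, prior, volume.voxel_um)
    rec = _record_from_mask(cell, 1, "cell_body", None, volume.voxel_um, frame)
    return LabeledObjects(cell.astype(np.int32), [rec], volume.voxel_um, frame)


def _fill_prior_cavities(cell, prior_points_um, voxel_um):
    """Fill complement regions that contain known pronucleus locations."""
    complement, n = ndimage.label(~cell, structure=_STRUCT_3D)
    cell_size = int(np.count_nonzero(cell))
    out = cell.copy()
    for point in prior_points_um:
        idx = tuple(
            int(np.clip(point[i] / voxel_um[i], 0, cell.shape[i] - 1)) for i in range(3)
        )
        if out[idx]:
            continue
        region = complement[idx]
        if region == 0:
            continue
        region_mask = complement == region
        if np.count_nonzero(region_mask) < 0.5 * cell_size:
            out |= region_mask
    return out


def _record_from_mask(mask, oid, cls, tag, voxel_um, frame) -> ObjectRecord:
    idx = np.nonzero(mask)
    count = idx[0].size
    centroid = tuple(float((idx[i].mean() + 0.5) * voxel_um[i]) for i in range(3))
    bbox = tuple(slice(int(idx[i].min()), int(idx[i].max()) + 1) for i in range(3))
    return ObjectRecord(oid, cls, tag, count, centroid, bbox, frame)


# --- nuclear objects --------------------------------------------------------


def _scale_search_order(params: SegmentationParams) -> np.ndarray:
    """Candidate Otsu scale factors, nearest to 1.0 first."""
    lo, hi = params.dynamic_otsu_bounds
    scales = np.arange(lo, hi + params.dynamic_otsu_step / 2, params.dynamic_otsu_step)
    return scales[np.argsort(np.abs(scales - 1.0), kind="stable")]


def _inertia_ellipsoid_marker(mask: np.ndarray, scale: float = 0.5) -> np.ndarray:
    """Voxels of the object's inertia ellipsoid shrunk by ``scale``."""
    idx = np.array(np.nonzero(mask), dtype=float)
    centroid = idx.mean(axis=1)
    centered = idx - centroid[:, None]
    cov = centered @ centered.T / idx.shape[1] + np.eye(3) * 0.25
    evals, evecs = np.linalg.eigh(cov)
    # ellipsoid with the same second moments has half-axes sqrt(5*eval)
    half_axes = np.sqrt(5.0 * evals) * scale
    coords = np.indices(mask.shape).reshape(3, -1).astype(float) - centroid[:, None]
    proj = evecs.T @ coords
    inside = (proj**2 / (half_axes[:, None] ** 2)).sum(axis=0) <= 1.0
    marker = inside.reshape(mask.shape) & mask
    if not marker.any():
        marker = np.zeros(mask.shape, dtype=bool)
        marker[tuple(np.round(centroid).astype(int))] = True
    return marker


def _axis_ratio(mask: np.ndarray, voxel_um) -> float:
    """Major/minor principal-axis ratio from second moments, in um space."""
    idx = np.array(np.nonzero(mask), dtype=float)
    idx *= np.asarray(voxel_um, dtype=float)[:, None]
    centered = idx - idx.mean(axis=1, keepdims=True)
    cov = centered @ centered.T / idx.shape[1]
    evals = np.linalg.eigvalsh(cov)
    evals = np.clip(evals, 1e-12, None)
    return float(np.sqrt(evals[-1] / evals[0]))


def detect_nuclear_objects(
    volume: VolumeImage,
    cell: LabeledObjects,
    prior: "LabeledObjects | Sequence[tuple[float, float, float]] | None" = None,
    params: SegmentationParams | None = None,
    frame: int = 0,
    cls: str = "pronucleus",
) -> LabeledObjects:
    """Detect dark nuclear objects inside the cell mask.

    The Otsu threshold within the cell is scaled over ``dynamic_otsu_bounds``
    (preferring scales near 1) until the dark class yields between 1 and
    ``max_candidates`` components of at least ``min_object_vox`` voxels.
    Candidates seed a marker-based watershed (markers: half-scale inertia
    ellipsoids; background: bright cytoplasm), holes are filled, and objects
    with no counterpart in the previous frame are rejected.  An empty result
    with ``disappeared=True`` models nuclear-envelope breakdown.
    """
    params = params or SegmentationParams()
    grid = volume.grid.astype(np.float32)
    if params.smoothing_sigma_vox > 0:
        grid = ndimage.gaussian_filter(grid, params.smoothing_sigma_vox)
    cell_mask = cell.mask()
    interior = cell_mask
    if params.cell_margin_vox > 0:
        size = 2 * params.cell_margin_vox + 1
        interior = ndimage.minimum_filter(cell_mask, size=size)
    inside = grid[interior]
    base_thr = _log_threshold_value(inside)
    candidates = None
    for scale in _scale_search_order(params):
        dark = (grid < base_thr * scale) & interior
        dark = ndimage.binary_opening(dark, structure=ball(1))
        labeled, n = ndimage.label(dark, structure=_STRUCT_3D)
        if n == 0:
            continue
        sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, np.arange(1, n + 1))
        size_cap = params.max_candidate_frac * np.count_nonzero(cell_mask)
        if sizes.max() >= size_cap:
            continue
        keep = np.flatnonzero(sizes >= params.min_object_vox) + 1
        if 1 <= keep.size <= params.max_candidates:
            candidates = [labeled == k for k in keep]
            break
    empty = LabeledObjects(
        np.zeros(grid.shape, dtype=np.int32), [], volume.voxel_um, frame,
        disappeared=True,
    )
    if candidates is None:
        return empty
    markers = np.zeros(grid.shape, dtype=np.int32)
    for i, cand in enumerate(candidates, start=1):
        markers[_inertia_ellipsoid_marker(cand)] = i
    background = grid > base_thr  # bright cytoplasm anchors the outside basin
    markers[background & cell_mask & (markers == 0)] = len(candidates) + 1
    ws = watershed(grid, markers=markers, mask=cell_mask)
    bright_mean = float(grid[interior & background].mean())
    labels = np.zeros(grid.shape, dtype=np.int32)
    records: list[ObjectRecord] = []
    next_id = 1
    for i in range(1, len(candidates) + 1):
        obj = ndimage.binary_fill_holes(ws == i, structure=_STRUCT_3D)
        if np.count_nonzero(obj) < params.min_object_vox:
            continue
        if float(grid[obj].mean()) * params.min_object_contrast > bright_mean:
            continue  # not genuinely dark: speckle tail, not a nucleus
        rec = _record_from_mask(obj, next_id, cls, None, volume.voxel_um, frame)
        if prior is not None and not _appears_in_prior(obj, rec, prior, params):
            continue
        rec.id = next_id
        labels[obj] = next_id
        records.append(rec)
        next_id += 1
    if not records:
        return empty
    return LabeledObjects(labels, records, volume.voxel_um, frame)


def _appears_in_prior(obj_mask, rec, prior, params: SegmentationParams) -> bool:
    """Previous-frame rule: IoU >= threshold OR centroid shift small enough."""
    centroid = np.asarray(rec.centroid_um)
    if isinstance(prior, LabeledObjects):
        for prev in prior.records:
            shift = float(np.linalg.norm(centroid - np.asarray(prev.centroid_um)))
            if shift <= params.overlap_accept_shift_um:
                return True
            inter = np.count_nonzero(obj_mask & prior.mask(prev.id))
            union = rec.voxel_count + prev.voxel_count - inter
            if union > 0 and inter / union >= params.overlap_accept_iou:
                return True
        return False
    # seed points act as zero-volume priors: distance rule only
    for point in prior:
        if np.linalg.norm(centroid - np.asarray(point)) <= params.overlap_accept_shift_um:
            return True
    return False


# --- events -----------------------------------------------------------------


def detect_merge(
    prev_objects: LabeledObjects,
    volume: VolumeImage,
    params: SegmentationParams | None = None,
) -> bool:
    """Two-threshold Otsu merge test.

    In the joint bounding region of the two previously tracked pronuclei the
    darkest of the three Otsu classes must form a single connected component
    containing both previous centroids.
    """
    params = params or SegmentationParams()
    if prev_objects.n_objects != 2:
        return False
    grid = volume.grid.astype(np.float32)
    if params.smoothing_sigma_vox > 0:
        grid = ndimage.gaussian_filter(grid, params.smoothing_sigma_vox)
    pad_vox = [int(np.ceil(5.0 / v)) for v in volume.voxel_um]
    sl = []
    for axis in range(3):
        lo = min(r.bbox[axis].start for r in prev_objects.records)
        hi = max(r.bbox[axis].stop for r in prev_objects.records)
        sl.append(slice(max(0, lo - pad_vox[axis]),
                        min(grid.shape[axis], hi + pad_vox[axis])))
    region = grid[tuple(sl)]
    hist = _histogram(region.ravel(), float(region.min()), float(region.max()))
    try:
        t1, _ = otsu_threshold_two(hist)
    except ValueError:
        return False
    edges = np.linspace(float(region.min()), float(region.max()), N_HIST_BINS + 1)
    dark = region <= edges[t1 + 1]
    labeled, n = ndimage.label(dark, structure=_STRUCT_3D)
    if n == 0:
        return False
    comp_ids = set()
    for rec in prev_objects.records:
        idx = tuple(
            int(np.clip(rec.centroid_um[i] / volume.voxel_um[i] - sl[i].start,
                        0, region.shape[i] - 1))
            for i in range(3)
        )
        comp_ids.add(int(labeled[idx]))
    return len(comp_ids) == 1 and 0 not in comp_ids


def detect_division(
    history: Sequence[LabeledObjects],
    params: SegmentationParams | None = None,
) -> tuple[bool, int | None]:
    """Flag nuclear division from shape jumps or object splits.

    Compares each frame with the most recent frame containing an object:
    division is flagged when the major/minor axis ratio of the largest
    object jumps by ``shape_change_ratio`` or the object count goes 1 -> 2.
    Returns ``(flag, frame_index_of_first_event)``.
    """
    params = params or SegmentationParams()
    prev_ratio = None
    prev_count = None
    for objs in history:
        if objs.n_objects == 0:
            continue
        biggest = max(objs.records, key=lambda r: r.voxel_count)
        ratio = _axis_ratio(objs.mask(biggest.id), objs.voxel_um)
        if prev_ratio is not None:
            if ratio / prev_ratio >= params.shape_change_ratio:
                return True, objs.frame
            if prev_count == 1 and objs.n_objects == 2:
                return True, objs.frame
        prev_ratio = ratio
        prev_count = objs.n_objects
    return False, None


# --- nucleoli ---------------------------------------------------------------


def detect_nucleoli(
    volume: VolumeImage,
    nucleus: LabeledObjects,
    params: SegmentationParams | None = None,
    frame: int = 0,
) -> LabeledObjects:
    """Adaptive-threshold nucleolus segmentation inside a nucleus mask.

    Intensities are normalized by the mean over the nucleus so the offset is
    scale-free; a voxel is nucleolar when it falls ``nucleolus_offset`` below
    its local mean (box window ``nucleolus_window_vox``).  Morphological
    closing merges adjacent fragments before components are extracted.
    """
    params = params or SegmentationParams()
    nuc_mask = nucleus.mask()
    if not nuc_mask.any():
        raise ValueError("empty nucleus mask")
    if params.nucleolus_margin_vox > 0:
        size = 2 * params.nucleolus_margin_vox + 1
        nuc_mask = ndimage.minimum_filter(nuc_mask, size=size)
    grid = volume.grid.astype(np.float32)
    mean_in = float(grid[nuc_mask].mean())
    if mean_in <= 0:
        return LabeledObjects(np.zeros(grid.shape, np.int32), [], volume.voxel_um, frame)
    norm = grid / mean_in
    local_mean = ndimage.uniform_filter(norm, size=params.nucleolus_window_vox)
    dark = (
        (norm < local_mean - params.nucleolus_offset)
        & (norm < params.nucleolus_max_frac)
        & nuc_mask
    )
    dark = ndimage.binary_closing(dark, structure=ball(params.closing_radius_vox))
    dark &= nuc_mask
    labeled, n = ndimage.label(dark, structure=_STRUCT_3D)
    labels = np.zeros(grid.shape, dtype=np.int32)
    records = []
    next_id = 1
    for i in range(1, n + 1):
        comp = labeled == i
        if np.count_nonzero(comp) < params.nucleolus_min_vox:
            continue
        comp = ndimage.binary_fill_holes(comp, structure=_STRUCT_3D)
        labels[comp] = next_id
        records.append(
            _record_from_mask(comp, next_id, "nucleolus", None, volume.voxel_um, frame)
        )
        next_id += 1
    return LabeledObjects(labels, records, volume.voxel_um, frame)


# --- tracking ---------------------------------------------------------------


def _match_tags(objects: LabeledObjects, prior: LabeledObjects) -> None:
    """Carry tags from the previous frame by greedy nearest-centroid matching."""
    unmatched = [r for r in objects.records if r.tag is None]
    available = [p for p in prior.records if p.tag is not None]
    pairs = []
    for rec in unmatched:
        for prev in available:
            d = np.linalg.norm(np.asarray(rec.centroid_um) - np.asarray(prev.centroid_um))
            pairs.append((float(d), rec, prev))
    pairs.sort(key=lambda p: p[0])
    taken_rec, taken_tag = set(), set()
    for d, rec, prev in pairs:
        if id(rec) in taken_rec or prev.tag in taken_tag:
            continue
        rec.tag = prev.tag
        taken_rec.add(id(rec))
        taken_tag.add(prev.tag)


def _process_frame(
    volume: VolumeImage,
    frame: int,
    prior: "LabeledObjects | Sequence | None",
    prior_points_um,
    params: SegmentationParams,
) -> LabeledObjects:
    cell = extract_cell_body(volume, params, prior=prior_points_um, frame=frame)
    return detect_nuclear_objects(volume, cell, prior=prior, params=params, frame=frame)


def track_sequence(
    volumes: Sequence[VolumeImage],
    seed: SeedAnnotation,
    params: SegmentationParams | None = None,
) -> TrackState:
    """Trace nuclear objects forward and backward from the seed frame.

    The seed frame is processed with the expert points as priors and each
    processed frame becomes the prior of the next, in both directions.
    Male/female identity is carried along the links; merge, division and
    disappearance events are recorded per frame.
    """
    params = params or SegmentationParams()
    n = len(volumes)
    if not (0 <= seed.frame_index < n):
        raise ValueError("seed frame outside sequence")
    state = TrackState()
    seed_points = list(seed.points_um.values())

    objs = _process_frame(volumes[seed.frame_index], seed.frame_index,
                          prior=seed_points, prior_points_um=seed_points, params=params)
    for tag, point in seed.points_um.items():
        containing = _object_containing(objs, point)
        if containing is None:
            raise ValueError(f"seed point {tag!r} not inside any detected object")
        if containing.tag is None:
            containing.tag = tag
    state.frames[seed.frame_index] = objs
    state.events[seed.frame_index] = FrameEvents()

    for direction in (+1, -1):
        prev = objs
        idx = seed.frame_index + direction
        while 0 <= idx < n:
            prior_points = [r.centroid_um for r in prev.records] or None
            cur = _process_frame(volumes[idx], idx, prior=prev,
                                 prior_points_um=prior_points, params=params)
            ev = FrameEvents()
            if cur.n_objects == 0:
                ev.disappeared = True
            else:
                _match_tags(cur, prev)
                if prev.n_objects == 2 and cur.n_objects == 1:
                    ev.merged = detect_merge(prev, volumes[idx], params)
                flag, _ = detect_division([prev, cur], params)
                # a merge also jumps the axis ratio; do not double-report
                ev.divided = flag and not ev.merged
            lo, hi = (prev, cur) if direction == 1 else (cur, prev)
            for rec in hi.records:
                if rec.tag is not None:
                    try:
                        state.add_link(lo.frame, lo.by_tag(rec.tag).id, hi.frame, rec.id)
                    except KeyError:
                        pass
            state.frames[idx] = cur
            state.events[idx] = ev
            if cur.n_objects > 0:
                prev = cur  # keep the last populated frame as prior across gaps
            idx += direction
    return state


def _object_containing(objects: LabeledObjects, point_um) -> ObjectRecord | None:
    idx = tuple(
        int(np.clip(point_um[i] / objects.voxel_um[i], 0,
                    objects.label_volume.shape[i] - 1))
        for i in range(3)
    )
    oid = int(objects.label_volume[idx])
    if oid > 0:
        for rec in objects.records:
            if rec.id == oid:
                return rec
    # tolerate a slightly off seed: nearest object whose equivalent-sphere
    # radius (plus a 5 um margin) still covers the point
    best, best_d = None, np.inf
    for rec in objects.records:
        d = float(np.linalg.norm(np.asarray(point_um) - np.asarray(rec.centroid_um)))
        if d <= _approx_radius(rec, objects) + 5.0 and d < best_d:
            best, best_d = rec, d
    return best


def _approx_radius(rec: ObjectRecord, objects: LabeledObjects) -> float:
    voxel_vol = float(np.prod(objects.voxel_um))
    return (3.0 * rec.voxel_count * voxel_vol / (4.0 * np.pi)) ** (1.0 / 3.0)
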