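"""Synthetic 4D zygote phantom with ground truth.

The phantom reproduces the statistical and geometric structure that the
averaging and segmentation stages assume from coherent imaging of mouse
zygotes and prophase-I oocytes:

* a bright, speckled cytoplasm containing a fine ER-like web and a few
  very bright lipid-droplet patches, inside a zona shell;
* uniformly grey, darker pronuclei (or a germinal-vesicle nucleus) with
  near-black nucleoli; nucleoli carry bright specular reflexes on the top
  and bottom of their border (normal-incidence back reflection);
* NSN / SN chromatin configurations — SN condenses chromatin into a bright
  ring around the nucleolus and lowers the remaining nucleoplasm signal,
  NSN keeps chromatin dispersed so the nucleus is brighter on average;
* pronuclear kinematics: growth plus mutual approach in control zygotes,
  growth without approach under microtubule depolymerization (nocodazole);
  scripted merge and first-division timelines.

Speckle is modelled at intensity level: each voxel carries a unit-mean
exponential multiplicative field, the squared magnitude of a complex
Gaussian that is spatially correlated at the PSF scale and evolves in time
as an AR(1) process with a per-compartment decorrelation constant (fast in
the stirred cytoplasm, slow in nuclei, quasi-static in nucleoli and
medium).  Averaging N volumes acquired more than a few cytoplasmic
decorrelation times apart therefore reduces cytoplasmic speckle contrast
toward 1/sqrt(N), which is the working principle of the DTIsp protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .ascan import axial_pixel_um
from .dtisp import ScanProtocol, Schedule, VolumeImage, build_schedule, temporal_average

# --- compartment catalogue --------------------------------------------------

LABELS: dict[str, int] = {
    "medium": 0,
    "zona": 1,
    "cytoplasm": 2,
    "er_web": 3,
    "lipid_droplet": 4,
    "pronucleus_m": 5,
    "pronucleus_f": 6,
    "nucleus": 7,
    "nucleolus": 8,
    "spindle_mt": 9,
    "chromosomes": 10,
}
LABEL_NAMES = {v: k for k, v in LABELS.items()}

#: amplitude reflectance per compartment; chosen to reproduce the observed
#: qualitative ordering (speckled white cytoplasm > grey pronuclei >
#: near-black nucleoli; ER web and lipid droplets brighter than cytoplasm).
DEFAULT_REFLECTANCE: dict[str, float] = {
    "medium": 0.02,
    "zona": 0.9,
    "cytoplasm": 1.0,
    "er_web": 1.6,
    "lipid_droplet": 2.5,
    "pronucleus_m": 0.35,
    "pronucleus_f": 0.35,
    "nucleus": 0.35,
    "nucleolus": 0.08,
    "spindle_mt": 0.25,
    "chromosomes": 0.7,
}

#: speckle decorrelation time constants, seconds (inf = static field)
DEFAULT_DECORRELATION_S: dict[str, float] = {
    "medium": np.inf,
    "zona": np.inf,
    "cytoplasm": 5.0,
    "er_web": 5.0,
    "lipid_droplet": 5.0,
    "pronucleus_m": 60.0,
    "pronucleus_f": 60.0,
    "nucleus": 60.0,
    "nucleolus": 600.0,
    "spindle_mt": 60.0,
    "chromosomes": 60.0,
}


@dataclass
class CompartmentSpec:
    """Optical properties of one compartment class."""

    label: str
    mean_reflectance: float
    decorrelation_time_s: float = np.inf

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown compartment label {self.label!r}")
        if self.mean_reflectance < 0:
            raise ValueError("mean_reflectance must be >= 0")


@dataclass
class NucleusSpec:
    """One nuclear object: a sphere with optional interior nucleoli."""

    tag: str                       # male | female | nucleus
    label: str                     # pronucleus_m | pronucleus_f | nucleus
    center0_um: tuple[float, float, float]   # (z, y, x) relative to cell centre
    radius0_um: float
    nucleoli: Sequence[tuple[tuple[float, float, float], float]] = field(
        default_factory=list
    )  # (offset zyx um, radius um)


@dataclass
class EmbryoPhantom:
    """Parametric geometry + optics + motion of one synthetic zygote/oocyte."""

    scenario: str = "custom"
    grid_shape: tuple[int, int, int] = (160, 128, 128)       # (z, y, x)
    voxel_um: tuple[float, float, float] = (axial_pixel_um(), 0.9, 0.9)
    cell_radius_um: float = 40.0
    cell_center_offset_um: tuple[float, float, float] = (0.0, 0.0, 0.0)
    zona_thickness_um: float = 7.0
    perivitelline_um: float = 0.0     # medium-filled gap between cell and zona
    nuclei: list[NucleusSpec] = field(default_factory=list)
    approach_speed_um_h: float = 10.0   # closing speed of the pronuclear separation
    growth_frac_per_2h: float = 0.15    # fractional volume growth per 2 h
    nocodazole: bool = False
    allow_overlap: bool = False          # merge scenario: let pronuclei interpenetrate
    chromatin_mode: str = "none"         # none | NSN | transition | SN
    ring_thickness_um: float = 2.5
    reflectance: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_REFLECTANCE))
    decorrelation_s: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DECORRELATION_S)
    )
    n_lipid_droplets: int = 25
    er_fraction: float = 0.08            # cytoplasm volume fraction of the ER web
    psf_sigma_vox: float = 0.9           # speckle grain size (PSF scale)
    specular_intensity: float = 2.5      # nucleolus top/bottom reflex bonus
    division_times_s: dict[str, float] | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.chromatin_mode not in ("none", "NSN", "transition", "SN"):
            raise ValueError(f"unknown chromatin mode {self.chromatin_mode!r}")
        import warnings

        extent = np.asarray(self.grid_shape) * np.asarray(self.voxel_um)
        outer = 2 * (self.cell_radius_um + self.perivitelline_um
                     + self.zona_thickness_um)
        if np.any(outer > extent):
            warnings.warn(
                "cell plus zona exceeds the field of view; the clipped poles "
                "can confuse cell-body extraction"
            )
        for nuc in self.nuclei:
            c = np.asarray(nuc.center0_um, dtype=float)
            if np.linalg.norm(c) + nuc.radius0_um > self.cell_radius_um + 1e-9:
                raise ValueError(f"nucleus {nuc.tag!r} extends outside the cell")

    @property
    def cell_center_um(self) -> np.ndarray:
        shape = np.asarray(self.grid_shape, dtype=float)
        voxel = np.asarray(self.voxel_um, dtype=float)
        return shape * voxel / 2.0 + np.asarray(self.cell_center_offset_um, dtype=float)

    # -- kinematics ----------------------------------------------------------

    def radius_at(self, nucleus: NucleusSpec, t_s: float) -> float:
        growth = 1.0 + self.growth_frac_per_2h * t_s / 7200.0
        return nucleus.radius0_um * growth ** (1.0 / 3.0)

    def _pronuclei(self) -> list[NucleusSpec]:
        return [n for n in self.nuclei if n.label.startswith("pronucleus")]

    def nuclear_centers_at(self, t_s: float) -> dict[str, np.ndarray]:
        """Analytic object centres (z, y, x um, absolute) at time ``t_s``."""
        centers = {
            n.tag: self.cell_center_um + np.asarray(n.center0_um, dtype=float)
            for n in self.nuclei
        }
        pn = self._pronuclei()
        if len(pn) == 2 and not self.nocodazole and self.approach_speed_um_h > 0:
            a = centers[pn[0].tag]
            b = centers[pn[1].tag]
            sep0 = float(np.linalg.norm(a - b))
            sep = sep0 - self.approach_speed_um_h * t_s / 3600.0
            floor = 0.0 if self.allow_overlap else (
                self.radius_at(pn[0], t_s) + self.radius_at(pn[1], t_s)
            )
            sep = max(sep, floor)
            mid = (a + b) / 2.0
            axis = (a - b) / sep0
            centers[pn[0].tag] = mid + axis * sep / 2.0
            centers[pn[1].tag] = mid - axis * sep / 2.0
        return centers

    def true_separation_um(self, t_s: float) -> float:
        pn = self._pronuclei()
        if len(pn) != 2:
            raise ValueError("separation defined only for two pronuclei")
        centers = self.nuclear_centers_at(t_s)
        return float(np.linalg.norm(centers[pn[0].tag] - centers[pn[1].tag]))


@dataclass
class GroundTruth:
    """Label volume plus an object table for one timepoint."""

    label_volume: np.ndarray          # uint8, same grid as VolumeImage
    objects: pd.DataFrame             # id, class, tag, centroid um, volume um3
    voxel_um: tuple[float, float, float]
    t_s: float

    def mask(self, label: str) -> np.ndarray:
        return self.label_volume == LABELS[label]

    def nuclear_mask(self) -> np.ndarray:
        """Nuclear objects with their interior (rings, nucleoli) included."""
        ids = [
            LABELS[name]
            for name in ("pronucleus_m", "pronucleus_f", "nucleus", "nucleolus",
                         "chromosomes")
        ]
        return np.isin(self.label_volume, ids)


# --- scenarios --------------------------------------------------------------

#: initial pronuclear separations, um: control vs. nocodazole-treated zygotes
CONTROL_INITIAL_SEPARATION_UM = 50.0
NOCODAZOLE_INITIAL_SEPARATION_UM = 30.0

SCENARIOS = (
    "fig5_control",
    "fig5_nocodazole",
    "division",
    "merge",
    "chromatin_NSN",
    "chromatin_SN",
    "chromatin_transition",
)


def _two_pronuclei(separation_um: float) -> list[NucleusSpec]:
    half = separation_um / 2.0
    nucleoli = lambda r: [((0.0, -4.0, 0.0), r), ((0.0, 4.5, 0.0), 0.75 * r)]
    return [
        NucleusSpec("male", "pronucleus_m", (0.0, 0.0, +half), 9.0, nucleoli(3.2)),
        NucleusSpec("female", "pronucleus_f", (0.0, 0.0, -half), 8.0, nucleoli(3.0)),
    ]


def make_scenario(name: str, **overrides) -> EmbryoPhantom:
    """Build a fully parameterized phantom for a named study condition."""
    if name == "fig5_control":
        ph = EmbryoPhantom(
            scenario=name,
            nuclei=_two_pronuclei(CONTROL_INITIAL_SEPARATION_UM),
            approach_speed_um_h=10.0,
        )
    elif name == "fig5_nocodazole":
        ph = EmbryoPhantom(
            scenario=name,
            nuclei=_two_pronuclei(NOCODAZOLE_INITIAL_SEPARATION_UM),
            nocodazole=True,
        )
    elif name == "merge":
        ph = EmbryoPhantom(
            scenario=name,
            nuclei=_two_pronuclei(24.0),
            approach_speed_um_h=40.0,
            allow_overlap=True,
        )
    elif name == "division":
        ph = EmbryoPhantom(
            scenario=name,
            nuclei=[
                NucleusSpec(
                    "nucleus", "nucleus", (0.0, 0.0, 0.0), 10.0,
                    [((0.0, -3.0, 0.0), 3.2), ((0.0, 3.5, 0.0), 2.8)],
                )
            ],
            division_times_s={
                "nucleoli_vanish_s": 600.0,
                "nebd_s": 1500.0,    # == elongate_s: no empty NEBD gap by default
                "elongate_s": 1500.0,
                "split_s": 1800.0,
            },
        )
    elif name in ("chromatin_NSN", "chromatin_SN", "chromatin_transition"):
        mode = name.split("_", 1)[1]
        refl = dict(DEFAULT_REFLECTANCE)
        # dispersed chromatin raises the whole nucleoplasm signal in NSN;
        # SN concentrates it into the peri-nucleolar ring instead
        refl["nucleus"] = {"NSN": 0.45, "transition": 0.38, "SN": 0.30}[mode]
        refl["chromosomes"] = 0.62
        ph = EmbryoPhantom(
            scenario=name,
            cell_radius_um=35.0,
            nuclei=[NucleusSpec("nucleus", "nucleus", (0.0, 0.0, 0.0), 12.5,
                                [((0.0, 1.0, 0.0), 4.5)])],
            approach_speed_um_h=0.0,
            growth_frac_per_2h=0.0,
            chromatin_mode=mode,
            reflectance=refl,
        )
    else:
        raise ValueError(f"unknown scenario {name!r}; one of {SCENARIOS}")
    if overrides:
        ph = replace(ph, **overrides)
    return ph


# --- rasterization ----------------------------------------------------------


def _coords_um(phantom: EmbryoPhantom) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Voxel-centre coordinates per axis, um (half-open voxel bins)."""
    voxel = phantom.voxel_um
    return tuple(
        (np.arange(n, dtype=np.float32) + 0.5) * voxel[i]
        for i, n in enumerate(phantom.grid_shape)
    )


def _paint_sphere(labels, coords, center, radius, value, out_mask=None):
    """Assign ``value`` inside a sphere, restricted to its bounding box."""
    z, y, x = coords
    sl = []
    for axis_coords, c in zip(coords, center):
        step = axis_coords[1] - axis_coords[0] if axis_coords.size > 1 else 1.0
        lo = int(max(0, np.floor((c - radius) / step - 1)))
        hi = int(min(axis_coords.size, np.ceil((c + radius) / step + 1)))
        sl.append(slice(lo, hi))
    zz = z[sl[0]][:, None, None] - center[0]
    yy = y[sl[1]][None, :, None] - center[1]
    xx = x[sl[2]][None, None, :] - center[2]
    inside = zz**2 + yy**2 + xx**2 <= radius**2
    labels[tuple(sl)][inside] = value
    if out_mask is not None:
        out_mask[tuple(sl)] |= inside


def _paint_shell(labels, coords, center, r_in, r_out, value, within=None, hemisphere=False):
    z, y, x = coords
    zz = (z - center[0])[:, None, None]
    yy = (y - center[1])[None, :, None]
    xx = (x - center[2])[None, None, :]
    d2 = zz**2 + yy**2 + xx**2
    shell = (d2 > r_in**2) & (d2 <= r_out**2)
    if hemisphere:
        shell &= yy > 0
    if within is not None:
        shell &= within
    labels[shell] = value


def _paint_ellipsoid(labels, coords, center, half_axes, value):
    z, y, x = coords
    zz = ((z - center[0]) / half_axes[0])[:, None, None]
    yy = ((y - center[1]) / half_axes[1])[None, :, None]
    xx = ((x - center[2]) / half_axes[2])[None, None, :]
    labels[zz**2 + yy**2 + xx**2 <= 1.0] = value


class _StaticBackground:
    """Time-independent labels (medium/zona/cytoplasm/ER/droplets), cached."""

    def __init__(self, phantom: EmbryoPhantom):
        coords = _coords_um(phantom)
        z, y, x = coords
        c = phantom.cell_center_um
        d2 = (
            (z - c[0])[:, None, None] ** 2
            + (y - c[1])[None, :, None] ** 2
            + (x - c[2])[None, None, :] ** 2
        )
        labels = np.full(phantom.grid_shape, LABELS["medium"], dtype=np.uint8)
        r_cell = phantom.cell_radius_um
        r_gap = r_cell + phantom.perivitelline_um
        labels[d2 <= (r_gap + phantom.zona_thickness_um) ** 2] = LABELS["zona"]
        labels[d2 <= r_gap**2] = LABELS["medium"]  # perivitelline space
        cyto = d2 <= r_cell**2
        labels[cyto] = LABELS["cytoplasm"]

        rng = np.random.default_rng(np.random.SeedSequence([phantom.rng_seed, 0xE5]))
        # ER web: thin level sets of a smooth random field -> filamentous sheets
        if phantom.er_fraction > 0:
            u = ndimage.gaussian_filter(
                rng.standard_normal(phantom.grid_shape).astype(np.float32), 2.2
            )
            thr = np.quantile(np.abs(u[cyto]), phantom.er_fraction)
            labels[cyto & (np.abs(u) < thr)] = LABELS["er_web"]
        # lipid droplets: small bright spheres scattered through the cytoplasm
        for _ in range(phantom.n_lipid_droplets):
            while True:
                pos = rng.uniform(-1, 1, size=3)
                if np.dot(pos, pos) <= 1.0:
                    break
            center = c + pos * 0.85 * r_cell
            _paint_sphere(labels, coords, center, rng.uniform(1.0, 2.2),
                          LABELS["lipid_droplet"])
        self.labels = labels
        self.coords = coords
        self.cytoplasm_d2 = d2


_BACKGROUND_CACHE: dict[int, tuple[EmbryoPhantom, _StaticBackground]] = {}


def _background(phantom: EmbryoPhantom) -> _StaticBackground:
    key = id(phantom)
    hit = _BACKGROUND_CACHE.get(key)
    if hit is not None and hit[0] is phantom:
        return hit[1]
    bg = _StaticBackground(phantom)
    _BACKGROUND_CACHE.clear()  # keep at most one phantom's background
    _BACKGROUND_CACHE[key] = (phantom, bg)
    return bg


def _division_phase(phantom: EmbryoPhantom, t_s: float) -> str:
    times = phantom.division_times_s
    if times is None:
        return "interphase"
    if t_s < times["nucleoli_vanish_s"]:
        return "interphase"
    if t_s < times["nebd_s"]:
        return "pre_nebd"
    if t_s < times["elongate_s"]:
        return "nebd"
    if t_s < times["split_s"]:
        return "elongated"
    return "divided"


#: post-division daughter geometry (radius, initial centre gap, separation speed)
_DAUGHTER_RADIUS_UM = 7.0
_DAUGHTER_GAP_UM = 18.0
_DAUGHTER_SPEED_UM_H = 10.0


def _nuclear_primitives(phantom: EmbryoPhantom, t_s: float) -> list[dict]:
    """Analytic nuclear objects present at ``t_s`` (scripted scenarios aware)."""
    phase = _division_phase(phantom, t_s)
    c = phantom.cell_center_um
    if phase == "interphase":
        centers = phantom.nuclear_centers_at(t_s)
        prims = []
        for nuc in phantom.nuclei:
            center = centers[nuc.tag]
            radius = phantom.radius_at(nuc, t_s)
            prims.append(
                dict(kind="sphere", tag=nuc.tag, cls=_class_of(nuc.label),
                     label=nuc.label, center=center, radius=radius,
                     nucleoli=[(center + np.asarray(off), r) for off, r in nuc.nucleoli])
            )
        return prims
    if phase == "pre_nebd":
        nuc = phantom.nuclei[0]
        return [dict(kind="sphere", tag=nuc.tag, cls="nucleus", label=nuc.label,
                     center=c, radius=phantom.radius_at(nuc, t_s), nucleoli=[])]
    if phase == "nebd":
        return [dict(kind="spindle", tag="spindle", cls="spindle", label="spindle_mt",
                     center=c, half_axes=(4.5, 9.0, 4.5), nucleoli=[])]
    if phase == "elongated":
        return [dict(kind="ellipsoid", tag="nucleus", cls="nucleus", label="nucleus",
                     center=c, half_axes=(6.5, 13.0, 6.5), nucleoli=[])]
    # divided
    dt_h = (t_s - phantom.division_times_s["split_s"]) / 3600.0
    gap = _DAUGHTER_GAP_UM + _DAUGHTER_SPEED_UM_H * dt_h
    prims = []
    for sign, tag in ((+1.0, "daughter_a"), (-1.0, "daughter_b")):
        center = c + np.array([0.0, sign * gap / 2.0, 0.0])
        prims.append(dict(kind="sphere", tag=tag, cls="nucleus", label="nucleus",
                          center=center, radius=_DAUGHTER_RADIUS_UM, nucleoli=[]))
    return prims


def _class_of(label: str) -> str:
    return "pronucleus" if label.startswith("pronucleus") else "nucleus"


def render_truth(phantom: EmbryoPhantom, t_s: float) -> GroundTruth:
    """Rasterize the phantom geometry at time ``t_s`` (deterministic).

    Every voxel receives exactly one compartment label; the object table
    lists the cell body and each nuclear object / nucleolus with its
    voxel-count volume and mask centroid.
    """
    bg = _background(phantom)
    labels = bg.labels.copy()
    coords = bg.coords
    voxel_vol = float(np.prod(phantom.voxel_um))
    prims = _nuclear_primitives(phantom, t_s)
    rows = []
    cell_mask_count = int(np.count_nonzero(bg.cytoplasm_d2 <= phantom.cell_radius_um**2))
    rows.append(_object_row(0, "cell_body", "cell", phantom.cell_center_um,
                            cell_mask_count * voxel_vol, t_s))
    next_id = 1
    for prim in prims:
        if prim["kind"] == "sphere":
            obj_mask = np.zeros(phantom.grid_shape, dtype=bool)
            _paint_sphere(labels, coords, prim["center"], prim["radius"],
                          LABELS[prim["label"]], out_mask=obj_mask)
            if phantom.chromatin_mode in ("SN", "transition"):
                for ncenter, nradius in prim["nucleoli"]:
                    _paint_shell(
                        labels, coords, ncenter, nradius,
                        nradius + phantom.ring_thickness_um, LABELS["chromosomes"],
                        within=obj_mask,
                        hemisphere=phantom.chromatin_mode == "transition",
                    )
            for ncenter, nradius in prim["nucleoli"]:
                nmask = np.zeros(phantom.grid_shape, dtype=bool)
                _paint_sphere(labels, coords, ncenter, nradius, LABELS["nucleolus"],
                              out_mask=nmask)
                rows.append(_mask_row(next_id, "nucleolus", prim["tag"], nmask,
                                      phantom.voxel_um, t_s))
                next_id += 1
            rows.append(_mask_row(next_id, prim["cls"], prim["tag"], obj_mask,
                                  phantom.voxel_um, t_s))
            next_id += 1
        elif prim["kind"] in ("ellipsoid", "spindle"):
            before = labels.copy()
            _paint_ellipsoid(labels, coords, prim["center"], prim["half_axes"],
                             LABELS[prim["label"]])
            obj_mask = labels != before
            if prim["kind"] == "spindle":
                # condensed chromosomes at the spindle equator
                _paint_sphere(labels, coords, prim["center"], 3.0,
                              LABELS["chromosomes"])
                obj_mask |= labels == LABELS["chromosomes"]
                rows.append(_mask_row(next_id, "spindle", prim["tag"], obj_mask,
                                      phantom.voxel_um, t_s))
            else:
                rows.append(_mask_row(next_id, prim["cls"], prim["tag"], obj_mask,
                                      phantom.voxel_um, t_s))
            next_id += 1
    table = pd.DataFrame(
        rows,
        columns=["object_id", "class", "tag", "cz_um", "cy_um", "cx_um",
                 "volume_um3", "t_s"],
    )
    return GroundTruth(labels, table, phantom.voxel_um, t_s)


def _object_row(oid, cls, tag, centroid, volume, t_s):
    return (oid, cls, tag, float(centroid[0]), float(centroid[1]),
            float(centroid[2]), float(volume), t_s)


def _mask_row(oid, cls, tag, mask, voxel_um, t_s):
    idx = np.nonzero(mask)
    count = idx[0].size
    centroid = [
        float((idx[i].mean() + 0.5) * voxel_um[i]) if count else np.nan
        for i in range(3)
    ]
    return (oid, cls, tag, *centroid, count * float(np.prod(voxel_um)), t_s)


# --- speckle ----------------------------------------------------------------


class SpeckleField:
    """Complex Gaussian speckle field with AR(1) temporal evolution.

    The real and imaginary parts are independent unit-variance Gaussian
    fields, spatially smoothed at the PSF scale and renormalized, so the
    intensity ``(re^2 + im^2)/2`` is unit-mean exponential at every voxel.
    ``advance`` evolves the field by ``rho = exp(-dt/tau)`` per voxel, with
    ``tau`` taken from the compartment occupying the voxel.
    """

    def __init__(self, phantom: EmbryoPhantom, rng: np.random.Generator):
        self.phantom = phantom
        self.rng = rng
        self.re = self._innovation()
        self.im = self._innovation()
        self.t_last: float | None = None

    def _innovation(self) -> np.ndarray:
        eps = self.rng.standard_normal(self.phantom.grid_shape).astype(np.float32)
        if self.phantom.psf_sigma_vox > 0:
            eps = ndimage.gaussian_filter(eps, self.phantom.psf_sigma_vox)
            eps /= eps.std()
        return eps

    def _tau_map(self, labels: np.ndarray) -> np.ndarray:
        lut = np.full(max(LABELS.values()) + 1, np.inf, dtype=np.float64)
        for name, idx in LABELS.items():
            lut[idx] = self.phantom.decorrelation_s.get(name, np.inf)
        return lut[labels]

    def advance(self, labels: np.ndarray, t_s: float) -> None:
        if self.t_last is None:
            self.t_last = t_s
            return
        dt = t_s - self.t_last
        self.t_last = t_s
        if dt <= 0:
            return
        with np.errstate(over="ignore"):
            rho = np.exp(-dt / self._tau_map(labels)).astype(np.float32)
        mix = np.sqrt(1.0 - rho**2)
        self.re = rho * self.re + mix * self._innovation()
        self.im = rho * self.im + mix * self._innovation()

    def intensity(self) -> np.ndarray:
        return 0.5 * (self.re**2 + self.im**2)


def _specular_mask(phantom: EmbryoPhantom, t_s: float) -> np.ndarray:
    """Top/bottom nucleolus border voxels carrying the specular reflex."""
    bg = _background(phantom)
    z, y, x = bg.coords
    mask = np.zeros(phantom.grid_shape, dtype=bool)
    shell_um = 1.5 * phantom.voxel_um[0]
    for prim in _nuclear_primitives(phantom, t_s):
        for center, radius in prim["nucleoli"]:
            zz = (z - center[0])[:, None, None]
            yy = (y - center[1])[None, :, None]
            xx = (x - center[2])[None, None, :]
            d = np.sqrt(zz**2 + yy**2 + xx**2)
            cap = (d <= radius) & (d >= radius - shell_um) & (np.abs(zz) >= 0.7 * radius)
            mask |= cap
    return mask


def render_volume(
    phantom: EmbryoPhantom,
    t_s: float,
    repeat_index: int = 0,
    rng: np.random.Generator | None = None,
    field: SpeckleField | None = None,
    truth: GroundTruth | None = None,
) -> VolumeImage:
    """One speckled intensity volume at time ``t_s``.

    Mean intensity per voxel is the squared compartment reflectance; the
    multiplicative speckle comes from ``field`` (or a freshly drawn one when
    only ``rng`` is given, in which case repeats are independent).
    Nucleolus top/bottom border caps receive a deterministic specular bonus.
    """
    if truth is None:
        truth = render_truth(phantom, t_s)
    if field is None:
        if rng is None:
            rng = np.random.default_rng(
                np.random.SeedSequence([phantom.rng_seed, int(t_s * 1e3) % (1 << 30),
                                        repeat_index])
            )
        field = SpeckleField(phantom, rng)
    lut = np.zeros(max(LABELS.values()) + 1, dtype=np.float32)
    for name, idx in LABELS.items():
        lut[idx] = phantom.reflectance.get(name, 0.0)
    mean_map = lut[truth.label_volume] ** 2
    intensity = mean_map * field.intensity()
    intensity[_specular_mask(phantom, t_s)] += phantom.specular_intensity
    return VolumeImage(intensity.astype(np.float32), phantom.voxel_um, t_s)


def simulate_session(
    phantom: EmbryoPhantom,
    protocol: ScanProtocol,
    rng: np.random.Generator | None = None,
    return_raw: bool = False,
):
    """Render every scheduled volume and apply the protocol's averaging.

    Returns ``(averaged_volumes, truths)`` with one ground truth at the
    centre of each temporal-averaging block (plus the raw volume list when
    ``return_raw``).  Speckle is carried through time by one AR(1) field, so
    consecutive volumes decorrelate according to each compartment's time
    constant and the volume period.
    """
    schedule: Schedule = build_schedule(protocol)
    vol_events = schedule.of_kind("volume")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([phantom.rng_seed, 0x5E55]))
    fld = SpeckleField(phantom, rng)
    raw: list[VolumeImage] = []
    for ev in vol_events:
        t = ev.t_start_s
        truth = render_truth(phantom, t)
        fld.advance(truth.label_volume, t)
        raw.append(render_volume(phantom, t, field=fld, truth=truth))
    averaged = temporal_average(raw, protocol.ta_window) if raw else []
    truths = [render_truth(phantom, v.timestamp_s) for v in averaged]
    if return_raw:
        return averaged, truths, raw
    return averaged, truths
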