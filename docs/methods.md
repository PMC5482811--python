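# Methods

`ocmtrack` models a spectral-domain optical coherence microscope (OCM)
imaging live mouse zygotes and prophase-I oocytes, and implements the
label-free analysis chain built on it: speckle reduction by multi-timescale
temporal compounding, automated segmentation and tracking of pronuclei and
nucleoli, and the derived kinetic and chromatin readouts.  This note
documents the models, the defaults and why they are what they are, and
what the synthetic data can and cannot stand in for.

## Depth reconstruction (`ocmtrack.ascan`)

A reflector at depth `z` modulates the source spectrum with fringes
`cos(2 k z)` in wavenumber `k = 2π/λ`; the depth profile (A-scan) is the
magnitude of the Fourier transform of the fringe after the standard chain:
fixed-pattern removal (per-pixel mean or a supplied reference), cubic
resampling from the spectrometer's wavelength grid onto uniform `k`,
residual dispersion correction, spectral shaping, FFT.

* **Calibration.** The instrument constants are 800 nm centre, 115 nm
  −3 dB bandwidth, 2048 spectral pixels, 140 kHz line rate.  The
  spectrometer span is not an independent constant here: the wavelength
  grid is synthesized so that the 1024 depth pixels span exactly 0.9 mm,
  making the nominal imaging range a configuration invariant (axial pixel
  900/1024 = 0.8789 µm).
* **Dispersion** is a polynomial phase `c2·(k−k0)² + c3·(k−k0)³` about the
  band centre (units µm², µm³ against `k` in rad/µm); correction multiplies
  the analytic signal (one-sided spectrum of the real fringe) by the
  conjugate phase.  ±500 fs² of group-delay dispersion corresponds to
  `c2 ≈ ±22.5 µm²`.
* **Windows.** Hann by default; a rectangular window is used wherever the
  Gaussian source envelope itself must be the shaping, e.g. when checking
  the closed-form coherence length `0.4413·λ₀²/Δλ ≈ 2.46 µm` in air.  The
  1.9 µm in-tissue figure is recorded but not re-derived (the tissue index
  is unspecified); the air value is the oracle.
* Depth index 0 is zero path delay, depths increase downward, pixel `i`
  covers `[i·δz, (i+1)·δz)`.  Peak localization uses the argmax; with the
  source background subtracted, isolated reflectors localize within one
  depth pixel across 10–800 µm.

## The scanning protocol (`ocmtrack.dtisp`)

Fully developed speckle has unit contrast (σ/µ of intensity); averaging N
independent looks lowers it to `1/√N`.  In a live cell the looks are
supplied by time itself: cytoplasmic motion decorrelates the speckle field
within seconds while the geometry barely moves, so revisiting each position
after milliseconds, seconds and tens of seconds and averaging yields
`≈1/√N` contrast in the cytoplasm without blurring structure.

* Schedules are built on integer-microsecond ticks: one volume per period
  from t = 0, `floor(session/period)` volumes in total, a timepoint event
  after each completed block of `ta_window` volumes (trailing,
  non-overlapping; the default window is 10).
* The per-protocol parameter tables of the original instrument are not
  public; the named presets (`dtisp1`–`dtisp5`) honour the documented
  constraints instead — 10 s volumes, 22–120 s periods, W = 10, a 30 s
  period for zygote kinetics, 120 s for long division sessions — and every
  number is overridable.
* Spatial compounding is a sliding, edge-clamped slab reduction
  (mean/min/max) along one axis at full lateral resolution; a 15 µm slab at
  the 0.879 µm axial pixel is 17 slices.
* Display mapping: linear divides by the 99.5th-percentile intensity and
  clips; logarithmic maps `10·log₁₀(I/I_ref)` (equal to 20·log₁₀ of the
  amplitude ratio) clipped at −40 dB and rescaled to [0, 1].  Linear
  display emphasizes cytoplasm, log display the darker nuclear interior.

## The synthetic zygote (`ocmtrack.phantom`)

The phantom provides what no deposited data set does: speckled 4D volumes
with voxel-exact ground truth.

* **Geometry.** A 40 µm-radius cell inside a 7 µm zona shell; two pronuclei
  (male 9 µm, female 8 µm at t = 0) each holding two nucleoli; an ER-like
  web rendered as the thin level set of a smoothed random field (≈8% of the
  cytoplasm volume); ~25 bright lipid droplets of 1–2.2 µm.  The default
  grid is 160×128×128 voxels at 0.879×0.9×0.9 µm (z × y × x); reduced
  studies use 128³ or 96³ with proportionally smaller cells.
* **Reflectance** (relative amplitude): medium 0.02, zona 0.9, cytoplasm
  1.0, ER web 1.6, lipid droplets 2.5, pronuclei 0.35, nucleoli 0.08,
  spindle 0.25, chromosomes 0.7.  These are invented to reproduce the
  observed orderings (white speckled cytoplasm, uniformly grey pronuclei,
  near-black nucleoli); only the orderings are data-backed.  The zona is
  rendered bright, contiguous with the cytoplasm: at pronuclear stages the
  perivitelline gap is below the PSF scale (a `perivitelline_um` parameter
  exists for experiments with a resolved gap).
* **Speckle.** Intensity-level model: each voxel carries
  `I = r²·|c|²/…` with `c` a complex Gaussian field, spatially smoothed at
  the PSF scale (σ = 0.9 voxels) and renormalized, so the marginal is exactly
  unit-mean exponential.  In time `c` is AR(1) per voxel with
  `ρ = exp(−Δt/τ)` and per-compartment constants τ: cytoplasm 5 s, nuclei
  60 s, nucleoli 600 s, medium/zona static.  The constants are invented —
  the phenomenon (cytoplasm decorrelates fast, nuclear interior slowly) is
  what the data show.  A field-level route through the A-scan simulator
  exists for cross-validation at small grids.
* **Specular reflexes.** The top and bottom caps of each nucleolus border
  (within 45° of the optical axis) receive a deterministic intensity bonus
  of 2.5, reproducing the bright reflexes that label nucleoli in the
  images.  Because they are imaging artifacts, downstream chromatin scoring
  excludes these polar cones.
* **Kinematics.** Pronuclei grow by +15% volume per 2 h (monotone, cube-root
  radius law — absolute growth rates are not standardized, so the
  rate is qualitative) and approach each other at 10 µm/h along the line of
  centres, clamped at contact; the nocodazole variant freezes the approach.
  Initial separations are 50 µm (control) and 30 µm (nocodazole).  Scripted
  scenarios: `merge` (fast approach with overlap allowed), `division`
  (nucleoli vanish → sudden elongation to axis ratio 2 → split into two
  daughters), and the GV-oocyte chromatin trio.
* **Chromatin modes.** NSN keeps chromatin dispersed (nucleoplasm
  reflectance 0.45); SN condenses it into a 2.5 µm ring of reflectance 0.62
  around the nucleolus over a darker 0.30 background; the transition mode
  rings one hemisphere at 0.38 background.  This reproduces both reported
  observations: a peri-nucleolar intensity peak in SN and a higher mean
  nuclear intensity in NSN.
* **What the phantom does not emulate:** depth-dependent attenuation and
  shadowing, refraction at the zona, optical aberrations, lipid-rich
  (porcine) cytoplasm, and genuine organelle motion (decorrelation stands
  in for it).  Tests passing on the phantom therefore validate the
  algorithmic chain under the stated statistical model, not performance on
  any particular instrument's data.

## Segmentation and tracking (`ocmtrack.segtrack`)

One expert annotation (the two pronucleus positions in a single frame)
initializes a forward/backward trace.  Per frame:

1. **Cell body** — per-slice Otsu threshold (256-bin histogram over the
   volume range) times a local factor, median-smoothed across z (window 5);
   2D hole filling per slice; 3D opening (ball radius 2); largest
   26-connected component; 3D cavity fill.  Cavities containing a prior
   frame's pronucleus are filled even when open to the boundary.
2. **Nuclear objects** — inside the cell mask (eroded by 3 voxels, since
   boundary voxels darkened by partial-volume mixing with the medium mimic
   nuclei), the base threshold is Otsu **on the log-intensity histogram**:
   dark nuclei occupy only a few percent of the cell, so a linear histogram
   is effectively unimodal and Otsu would split the bright cytoplasm mode;
   in log scale the two modes have comparable width and the valley wins.
   The threshold scale is then searched over [0.7, 1.3] (nearest 1.0 first)
   until the dark class yields 1–4 components of ≥200 voxels, none larger
   than 20% of the cell (a larger component means the threshold crossed
   into the cytoplasm).  Components become half-scale inertia-ellipsoid
   markers for a watershed on the smoothed intensity with a bright-cytoplasm
   background marker; holes are filled; objects are kept only if their mean
   intensity is at least a factor 2 below the bright-class mean (nuclei are
   uniformly grey, not speckle dips) and, except at the seed frame, if they
   appeared in the previous frame (IoU ≥ 0.05 or centroid shift ≤ 10 µm).
   No candidate at any scale returns an empty, flagged result — the
   nuclear-envelope-breakdown case.
3. **Merge** — two-threshold (3-class) Otsu in the dilated joint bounding
   box of the two tracked pronuclei; merged when the darkest class is one
   connected component containing both previous centroids.
4. **Division** — the major/minor principal-axis ratio (from second
   moments in µm space) of the largest nuclear object jumps by ≥1.5×
   between populated frames, or one object splits into two accepted ones.
   A frame explained by a merge is not also reported as a division.
5. **Nucleoli** — intensities normalized by the mean over the nucleus mask
   (eroded by 2 voxels to avoid the bright watershed rim); a voxel is
   nucleolar when it is 0.05 below its local mean (7-voxel box) *and* below
   0.35 of the nuclear mean ("near-black"); closing with ball radius 1
   merges adjacent fragments; components ≥30 voxels are kept.

Both Otsu variants are exact maximizers of between-class variance with
ties broken toward the lowest bin; note that over an empty histogram valley
the criterion is flat, so the reported threshold is the valley's lower
edge.  All detectors are invariant under positive intensity scaling.
Connectivity is 26-neighbourhood in 3D, 8 in 2D.  Spindle vs. nucleus is a
context flag (post-NEBD), not an appearance classification.

Identity (male/female) propagates by greedy nearest-centroid matching
frame to frame; across an empty (NEBD) gap the last populated frame serves
as prior.

## Quantification (`ocmtrack.quantify`)

Volumes are exact voxel counts times the voxel volume; centroids are
unweighted mask centroids; velocity is a centred finite difference over a
3-timepoint window in µm/min.  The inter-pronuclear distance series is the
Euclidean centroid distance at shared timepoints.  Line profiles use
trilinear interpolation at sub-voxel steps; the default line is the nuclear
diameter through a nucleolus (profile placement conventions are described
inconsistently — perimeter vs. diameter — so the line is user-specified
with this helper as default).  The chromatin score is the mean intensity of
a 2-voxel shell around the nucleoli (excluding the 45° polar cones that
carry the specular reflexes) divided by the mean of the remaining
nucleoplasm; classes are NSN < 1.1 ≤ transition ≤ 1.4 < SN.  The class
thresholds are package defaults — only the ordinal structure (ring present
vs. absent, NSN brighter on average) is data-backed.

## Numerical and design notes

* Averaging blocks are trailing and non-overlapping; partial blocks drop.
* B-scan (millisecond) repeats are folded into volume synthesis: at ms
  intervals cytoplasmic speckle barely decorrelates (ρ ≈ 0.8), so separate
  repeat rendering would add cost without statistical effect.
* Volume TIFFs default to byte-deterministic shaped metadata so a run's
  manifest checksums reproduce exactly; `.ome.tif` paths switch to OME
  export (which embeds a fresh UUID per write).
* Cell-mask boundaries are biased outward by ~0.3 voxels (smoothing plus
  threshold placement), i.e. +2–3% volume for a 15 µm sphere; recovery is
  within 10% for cells ≥ 12 µm radius, degrading for much smaller objects.
* The acceptance recomputation and the heavier tests run at reduced problem
  sizes — 128³ session grids, 96³ scenario grids with 30 µm cells, 64³
  sphere and false-positive studies, 20 timepoints per kinetics session —
  chosen as the smallest sizes at which the measured quantities are stable.
* The power density 1.27×10⁴ W/cm² and the 20 µs sensitivity exposure are
  recorded constants; neither follows from the other instrument constants, so
  they are not re-derived.  The line period defaults to 1/140 kHz.

## Known limitations

* The segmentation chain implements the documented main algorithm steps;
  the original instrument software's additional refinements are not public
  and are not reproduced.
* Appearance-based spindle recognition, multi-cell (blastocyst) counting
  and cohort-level statistics are out of scope.
* With single-look (unaveraged) input the dark-class statistics degrade;
  the detectors assume the protocol's temporal averaging (W ≥ 5).
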