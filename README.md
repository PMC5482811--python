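# ocmtrack

Label-free 4D imaging of early mammalian embryos with optical coherence
microscopy (OCM), as a tested, reproducible pipeline: spectral-domain
depth reconstruction, speckle reduction by multi-timescale temporal
compounding, a synthetic zygote phantom with voxel-exact ground truth,
and automated segmentation, tracking and quantification of pronuclei and
nucleoli.

**Who it is for.** Researchers building or evaluating coherent-imaging
analysis for embryology — anyone who needs to test nucleus segmentation,
merge/division detection or speckle-averaging protocols against ground
truth that real OCM recordings cannot provide.

## The science in brief

*Reconstruction.* A reflector at depth `z` imprints fringes `cos(2kz)` on
the source spectrum (`k = 2π/λ`). The depth profile is recovered by
fixed-pattern removal → resampling to uniform `k` → residual dispersion
correction → spectral shaping → Fourier transform. With an 800 nm, 115 nm
FWHM Gaussian source the axial point-spread FWHM is
`0.4413·λ₀²/Δλ ≈ 2.46 µm` in air; 2048-pixel spectra give 1024 depth
pixels over 0.9 mm (0.879 µm per pixel).

*Speckle averaging.* Fully developed speckle intensity is exponential with
contrast σ/µ = 1; averaging N independent looks gives `1/√N`. Cytoplasmic
motion decorrelates the speckle within seconds while structure is static,
so revisiting each position after milliseconds, seconds and tens of
seconds and averaging (ten volumes by default) drops cytoplasm contrast to
≈ 0.32 and makes nuclei (uniform grey), nucleoli (near-black, with
specular reflexes at their top/bottom borders) and the ER web visible
without any label.

*Tracking.* From a single expert annotation of the two pronuclei the
algorithm traces forward and backward in time: cell-body extraction
(per-slice Otsu, hole filling, opening, largest component, cavity fill),
dynamically tuned dark-object thresholding with ellipsoid-seeded watershed,
previous-frame consistency, two-threshold Otsu merge detection, shape-jump
division detection, and adaptive-threshold nucleolus segmentation. Volumes,
positions, velocities, inter-pronuclear distances and NSN/SN chromatin
ring scores follow from the tracked masks.

## Worked example

Simulate a control zygote (initial pronuclear separation 50 µm), average
one ten-volume DTIsp timepoint, track from the expert seed, and measure
the inter-pronuclear distance:

```python
import numpy as np
from ocmtrack import (ScanProtocol, SeedAnnotation, make_scenario,
                      simulate_session, map_intensity, track_sequence,
                      measure_objects, pairwise_distance_series)

phantom = make_scenario("fig5_control", rng_seed=1, grid_shape=(128, 128, 128))
protocol = ScanProtocol(name="demo", volume_period_s=30, ta_window=10,
                        session_duration_s=1200, volume_duration_s=10)
volumes, truths = simulate_session(phantom, protocol)       # 4 averaged timepoints
display = [map_intensity(v, "linear") for v in volumes]

pn = truths[0].objects.query("`class` == 'pronucleus'")
seed = SeedAnnotation(0, {r.tag: (r.cz_um, r.cy_um, r.cx_um)
                          for r in pn.itertuples()})
track = track_sequence(display, seed)
trajs = measure_objects(track, {i: v.timestamp_s for i, v in enumerate(volumes)})
print(pairwise_distance_series(trajs["male"], trajs["female"]))
```

Output:

```
     t_s  distance_um
0  135.0    49.640291
1  435.0    48.743890
2  735.0    48.024085
3 1035.0    47.126765
```

Each row is one averaged timepoint (timestamp = centre of its ten-volume
block). The measured distance starts at the configured 50 µm separation
(49.64 µm measured; segmentation is accurate to a fraction of a voxel) and
decreases at the phantom's 10 µm/h approach speed — the control-zygote
behaviour. The nocodazole scenario (`fig5_nocodazole`, initial separation
30 µm, approach abolished) yields a flat series.

A command-line interface wraps the same stages
(`ocmtrack simulate | reconstruct | average | project | track | pipeline`);
`ocmtrack pipeline --config run.yaml` executes the whole chain and writes
volumes, label maps, event logs, trajectory/distance CSVs and a
checksummed manifest.

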