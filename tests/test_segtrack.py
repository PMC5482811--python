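"""Otsu oracles, cell/nucleus segmentation accuracy, event detection, tracking."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage

from ocmtrack.dtisp import VolumeImage, map_intensity
from ocmtrack.phantom import (
    DEFAULT_REFLECTANCE,
    EmbryoPhantom,
    LABELS,
    NucleusSpec,
    make_scenario,
    simulate_session,
)
from ocmtrack.segtrack import (
    LabeledObjects,
    SeedAnnotation,
    SegmentationParams,
    _axis_ratio,
    detect_division,
    detect_merge,
    detect_nucleoli,
    detect_nuclear_objects,
    extract_cell_body,
    otsu_threshold,
    otsu_threshold_two,
    track_sequence,
)

from conftest import SMALL_CELL, one_timepoint_protocol, seed_from_truth


# --- independent exhaustive oracles ----------------------------------------


def otsu_exhaustive(hist):
    """Explicit between-class-variance search, tie to the lowest bin."""
    hist = np.asarray(hist, dtype=float)
    bins = np.arange(hist.size, dtype=float)
    best, best_t = -1.0, None
    for t in range(hist.size - 1):
        w0, w1 = hist[: t + 1].sum(), hist[t + 1 :].sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[: t + 1] * bins[: t + 1]).sum() / w0
        mu1 = (hist[t + 1 :] * bins[t + 1 :]).sum() / w1
        v = w0 * w1 * (mu0 - mu1) ** 2
        if v > best:
            best, best_t = v, t
    return best_t


def otsu2_exhaustive(hist):
    hist = np.asarray(hist, dtype=float)
    bins = np.arange(hist.size, dtype=float)
    best, best_pair = -1.0, None
    for t1 in range(hist.size - 2):
        for t2 in range(t1 + 1, hist.size - 1):
            parts = (hist[: t1 + 1], hist[t1 + 1 : t2 + 1], hist[t2 + 1 :])
            bparts = (bins[: t1 + 1], bins[t1 + 1 : t2 + 1], bins[t2 + 1 :])
            if any(p.sum() == 0 for p in parts):
                continue
            crit = sum((p * b).sum() ** 2 / p.sum() for p, b in zip(parts, bparts))
            if crit > best:
                best, best_pair = crit, (t1, t2)
    return best_pair


class TestOtsu:
    def test_symmetric_bimodal_ties_to_lowest_bin(self):
        hist = np.zeros(256)
        hist[0] = 50
        hist[255] = 50
        assert otsu_threshold(hist) == 0

    def test_two_gaussians_threshold_in_valley(self):
        rng = np.random.default_rng(0)
        values = np.concatenate(
            [rng.normal(50, 10, 10_000), rng.normal(200, 10, 10_000)]
        )
        hist, _ = np.histogram(np.clip(values, 0, 255), bins=256, range=(0, 256))
        t = otsu_threshold(hist)
        # the criterion is flat across the empty valley; tie-break-lowest
        # lands on its lower edge, between the two modes
        assert 50 < t < 200
        assert t == otsu_exhaustive(hist)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(1)
        hist = np.zeros(256)
        hist[20:80] = rng.integers(0, 100, 60)
        hist[150:200] = rng.integers(0, 100, 50)
        shifted = np.roll(hist, 10)
        assert otsu_threshold(shifted) == otsu_threshold(hist) + 10

    def test_single_bin_histogram_rejected(self):
        hist = np.zeros(256)
        hist[7] = 100
        with pytest.raises(ValueError):
            otsu_threshold(hist)

    def test_trimodal_two_thresholds_bracket_the_modes(self):
        rng = np.random.default_rng(2)
        values = np.concatenate(
            [rng.normal(30, 8, 8000), rng.normal(120, 8, 8000), rng.normal(220, 8, 8000)]
        )
        hist, _ = np.histogram(np.clip(values, 0, 255), bins=256, range=(0, 256))
        t1, t2 = otsu_threshold_two(hist)
        assert 30 < t1 < 120 < t2 < 220  # thresholds bracket the three modes
        assert (t1, t2) == otsu2_exhaustive(hist)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_single_threshold_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        hist = rng.integers(0, 50, 256)
        hist[rng.integers(0, 256, 4)] += rng.integers(100, 1000, 4).astype(hist.dtype)
        assert otsu_threshold(hist) == otsu_exhaustive(hist)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_two_thresholds_match_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        hist = rng.integers(0, 20, 64)  # smaller histogram: O(n^2) oracle
        hist[rng.integers(0, 64, 3)] += rng.integers(50, 500, 3).astype(hist.dtype)
        if np.count_nonzero(hist) < 3:
            hist[:3] += 1
        assert otsu_threshold_two(hist) == otsu2_exhaustive(hist)


# --- cell body --------------------------------------------------------------


def sphere_phantom(radius_um=18.0, seed=0, ratio=10.0, offset=(0, 0, 0)):
    refl = dict(DEFAULT_REFLECTANCE)
    refl["medium"] = 1.0 / np.sqrt(ratio)
    return EmbryoPhantom(
        grid_shape=(64, 64, 64), cell_radius_um=radius_um,
        cell_center_offset_um=tuple(offset), zona_thickness_um=0.0,
        n_lipid_droplets=0, er_fraction=0.0, reflectance=refl, rng_seed=seed,
    )


def averaged_display(phantom):
    vols, truths = simulate_session(phantom, one_timepoint_protocol())
    return map_intensity(vols[0], "linear"), truths[0]


class TestCellBody:
    def test_speckled_sphere_recovered_within_10_percent(self):
        ph = sphere_phantom(radius_um=18.0, seed=42, offset=(2.0, -1.5, 1.0))
        display, truth = averaged_display(ph)
        cell = extract_cell_body(display)
        true_vox = int((truth.label_volume == LABELS["cytoplasm"]).sum())
        rec = cell.records[0]
        assert rec.voxel_count == pytest.approx(true_vox, rel=0.10)
        true_c = truth.objects.iloc[0][["cz_um", "cy_um", "cx_um"]].to_numpy(float)
        err_vox = np.abs(np.asarray(rec.centroid_um) - true_c) / np.asarray(ph.voxel_um)
        assert err_vox.max() <= 1.0

    def test_dark_pronucleus_cavity_is_filled(self, fig5_display):
        _, display, truth = fig5_display
        cell = extract_cell_body(display)
        pn = np.isin(
            truth.label_volume,
            [LABELS["pronucleus_m"], LABELS["pronucleus_f"], LABELS["nucleolus"]],
        )
        assert (pn & ~cell.mask()).sum() / pn.sum() < 0.02

    def test_two_disjoint_cells_keep_the_larger(self):
        rng = np.random.default_rng(3)
        grid = 0.05 * rng.exponential(1.0, (60, 60, 60)).astype(np.float32)
        z, y, x = np.indices(grid.shape)
        big = (z - 30) ** 2 + (y - 30) ** 2 + (x - 18) ** 2 <= 14**2
        small = (z - 30) ** 2 + (y - 30) ** 2 + (x - 48) ** 2 <= 7**2
        for mask in (big, small):
            grid[mask] = rng.exponential(1.0, int(mask.sum()))
        vol = map_intensity(VolumeImage(grid, (1, 1, 1)), "linear")
        cell = extract_cell_body(vol)
        overlap_big = (cell.mask() & big).sum() / big.sum()
        overlap_small = (cell.mask() & small).sum() / small.sum()
        assert overlap_big > 0.8 and overlap_small < 0.05

    def test_masks_invariant_under_intensity_scaling(self):
        ph = sphere_phantom(radius_um=15.0, seed=7)
        display, _ = averaged_display(ph)
        scaled = VolumeImage(display.grid * 3.7, display.voxel_um,
                             display.timestamp_s, display.mapping_state)
        a = extract_cell_body(display)
        b = extract_cell_body(scaled)
        np.testing.assert_array_equal(a.label_volume, b.label_volume)

    def test_flat_volume_rejected(self):
        vol = VolumeImage(np.zeros((10, 10, 10)), (1, 1, 1))
        with pytest.raises(ValueError):
            extract_cell_body(vol)


# --- nuclear objects --------------------------------------------------------


class TestNuclearObjects:
    def test_two_pronuclei_found_within_2_um(self, fig5_display):
        ph, display, truth = fig5_display
        cell = extract_cell_body(display)
        objs = detect_nuclear_objects(display, cell)
        assert objs.n_objects == 2
        pn = truth.objects[truth.objects["class"] == "pronucleus"]
        true_centers = pn[["cz_um", "cy_um", "cx_um"]].to_numpy(float)
        for rec in objs.records:
            d = np.linalg.norm(true_centers - np.asarray(rec.centroid_um), axis=1)
            assert d.min() <= 2.0

    def test_masks_invariant_under_intensity_scaling(self, fig5_display):
        _, display, _ = fig5_display
        cell = extract_cell_body(display)
        a = detect_nuclear_objects(display, cell)
        scaled = VolumeImage(display.grid * 0.37, display.voxel_um,
                             display.timestamp_s, display.mapping_state)
        b = detect_nuclear_objects(scaled, extract_cell_body(scaled))
        np.testing.assert_array_equal(a.label_volume, b.label_volume)

    def test_transient_blob_absent_from_prior_is_rejected(self, fig5_display):
        _, display, _ = fig5_display
        grid = display.grid.copy()
        # implant a transient dark blob far from both pronuclei
        z, y, x = np.indices(grid.shape)
        blob = (z - 80) ** 2 + (y - 40) ** 2 + (x - 64) ** 2 <= 6**2
        grid[blob] *= 0.05
        vol = VolumeImage(grid, display.voxel_um, display.timestamp_s,
                          display.mapping_state)
        cell = extract_cell_body(vol)
        without_prior = detect_nuclear_objects(vol, cell)
        prior = detect_nuclear_objects(display, extract_cell_body(display))
        with_prior = detect_nuclear_objects(vol, cell, prior=prior)
        assert without_prior.n_objects == 3
        assert with_prior.n_objects == 2

    def test_cell_without_nuclei_flags_disappearance(self):
        """No dark candidate at any threshold scale (the NEBD situation)."""
        ph = sphere_phantom(radius_um=18.0, seed=9)
        display, _ = averaged_display(ph)
        cell = extract_cell_body(display)
        objs = detect_nuclear_objects(display, cell)
        assert objs.n_objects == 0
        assert objs.disappeared


# --- events -----------------------------------------------------------------


class TestEvents:
    def test_merge_scenario_flags_at_contact(self):
        ph = make_scenario("merge", rng_seed=4, **SMALL_CELL)
        proto = one_timepoint_protocol(period_s=60.0, ta_window=5)
        proto = type(proto)(
            name="merge", volume_period_s=60.0, ta_window=5,
            session_duration_s=1800.0, volume_duration_s=10.0,
        )
        vols, truths = simulate_session(ph, proto)
        display = [map_intensity(v, "linear") for v in vols]
        track = track_sequence(display, seed_from_truth(truths[0]))
        # scripted contact: first timepoint where separation < summed radii
        contact = next(
            i for i, v in enumerate(vols)
            if ph.true_separation_um(v.timestamp_s)
            < ph.radius_at(ph.nuclei[0], v.timestamp_s)
            + ph.radius_at(ph.nuclei[1], v.timestamp_s)
        )
        flagged = [f for f in track.frame_indices() if track.events[f].merged]
        assert flagged and abs(flagged[0] - contact) <= 1

    def test_control_scenario_never_merges(self, fig5_display):
        _, display, _ = fig5_display
        cell = extract_cell_body(display)
        objs = detect_nuclear_objects(display, cell)
        assert detect_merge(objs, display) is False

    def test_division_flag_within_one_frame_of_split(self, division_track):
        ph, vols, truths, track = division_track
        split_frame = next(
            i for i, t in enumerate(truths) if (t.objects["class"] == "nucleus").sum() == 2
        )
        flagged = [f for f in track.frame_indices() if track.events[f].divided]
        assert flagged and min(abs(f - split_frame) for f in flagged) <= 1

    def test_sphere_axis_ratio_near_unity(self):
        z, y, x = np.indices((40, 40, 40))
        mask = (z - 20) ** 2 + (y - 20) ** 2 + (x - 20) ** 2 <= 15**2
        assert _axis_ratio(mask, (1.0, 1.0, 1.0)) == pytest.approx(1.0, abs=0.05)

    def test_static_nucleus_raises_no_events(self):
        ph = EmbryoPhantom(
            grid_shape=(64, 64, 64), cell_radius_um=20.0, zona_thickness_um=3.0,
            n_lipid_droplets=6,
            nuclei=[NucleusSpec("nucleus", "nucleus", (0.0, 0.0, 0.0), 8.0)],
            growth_frac_per_2h=0.0, rng_seed=17,
        )
        proto = type(one_timepoint_protocol())(
            name="static", volume_period_s=30.0, ta_window=5,
            session_duration_s=1500.0, volume_duration_s=10.0,
        )
        vols, truths = simulate_session(ph, proto)
        display = [map_intensity(v, "linear") for v in vols]
        track = track_sequence(display, seed_from_truth(truths[0]))
        for f in track.frame_indices():
            ev = track.events[f]
            assert not (ev.merged or ev.divided or ev.disappeared)


# --- nucleoli ---------------------------------------------------------------


class TestNucleoli:
    def test_three_nucleoli_recovered(self):
        ph = EmbryoPhantom(
            grid_shape=(96, 96, 96), cell_radius_um=30.0, zona_thickness_um=5.0,
            n_lipid_droplets=8,
            nuclei=[NucleusSpec(
                "nucleus", "nucleus", (0.0, 0.0, 0.0), 13.0,
                [((0.0, -7.0, 0.0), 3.2), ((0.0, 7.0, 0.0), 3.0),
                 ((0.0, 0.0, 7.5), 3.1)],
            )],
            growth_frac_per_2h=0.0, rng_seed=23,
        )
        display, truth = averaged_display_from(ph)
        cell = extract_cell_body(display)
        nucleus = detect_nuclear_objects(display, cell, cls="nucleus")
        found = detect_nucleoli(display, nucleus)
        assert found.n_objects == 3
        truth_nucl = truth.objects[truth.objects["class"] == "nucleolus"]
        true_centers = truth_nucl[["cz_um", "cy_um", "cx_um"]].to_numpy(float)
        for rec in found.records:
            d = np.linalg.norm(true_centers - np.asarray(rec.centroid_um), axis=1)
            assert d.min() <= 1.5

    def test_homogeneous_nucleus_yields_none(self):
        ph = EmbryoPhantom(
            grid_shape=(64, 64, 64), cell_radius_um=20.0, zona_thickness_um=3.0,
            n_lipid_droplets=0, er_fraction=0.0,
            nuclei=[NucleusSpec("nucleus", "nucleus", (0.0, 0.0, 0.0), 9.0)],
            growth_frac_per_2h=0.0, rng_seed=29,
        )
        display, _ = averaged_display_from(ph)
        cell = extract_cell_body(display)
        nucleus = detect_nuclear_objects(display, cell, cls="nucleus")
        found = detect_nucleoli(display, nucleus)
        assert found.n_objects == 0

    def test_adjacent_dark_bodies_merge_after_closing(self):
        """Two dark blobs one voxel apart close into a single nucleolus."""
        grid = np.full((40, 40, 40), 0.5, dtype=np.float32)
        z, y, x = np.indices(grid.shape)
        nucleus_mask = (z - 20) ** 2 + (y - 20) ** 2 + (x - 20) ** 2 <= 15**2
        a = (z - 20) ** 2 + (y - 16) ** 2 + (x - 20) ** 2 <= 3.0**2
        b = (z - 20) ** 2 + (y - 23) ** 2 + (x - 20) ** 2 <= 3.0**2
        grid[a | b] = 0.01
        assert not np.any(a & b)  # distinct bodies, one voxel apart
        vol = VolumeImage(grid, (1, 1, 1), mapping_state="linear_display")
        nucleus = LabeledObjects(nucleus_mask.astype(np.int32), [], (1, 1, 1))
        params = SegmentationParams(nucleolus_min_vox=20)
        found = detect_nucleoli(vol, nucleus, params)
        assert found.n_objects == 1


def averaged_display_from(phantom):
    vols, truths = simulate_session(phantom, one_timepoint_protocol())
    return map_intensity(vols[0], "linear"), truths[0]


# --- tracking ---------------------------------------------------------------


@pytest.fixture(scope="module")
def short_control_track():
    ph = make_scenario("fig5_control", rng_seed=1, grid_shape=(128, 128, 128))
    proto = type(one_timepoint_protocol())(
        name="short", volume_period_s=30.0, ta_window=10,
        session_duration_s=1200.0, volume_duration_s=10.0,
    )
    vols, truths = simulate_session(ph, proto)
    display = [map_intensity(v, "linear") for v in vols]
    seed = seed_from_truth(truths[1], frame_index=1)
    return ph, display, truths, track_sequence(display, seed)


class TestTracking:
    def test_identities_preserved_without_swaps(self, short_control_track):
        ph, display, truths, track = short_control_track
        for frame, truth in enumerate(truths):
            objs = track.frames[frame]
            pn = truth.objects[truth.objects["class"] == "pronucleus"]
            for _, row in pn.iterrows():
                rec = objs.by_tag(row["tag"])
                d = np.linalg.norm(
                    np.asarray(rec.centroid_um)
                    - row[["cz_um", "cy_um", "cx_um"]].to_numpy(float)
                )
                assert d <= 2.0  # matched to the correct pronucleus

    def test_forward_pass_is_deterministic(self, short_control_track):
        ph, display, truths, track = short_control_track
        seed = seed_from_truth(truths[1], frame_index=1)
        again = track_sequence(display, seed)
        for frame in track.frame_indices():
            np.testing.assert_array_equal(
                track.frames[frame].label_volume, again.frames[frame].label_volume
            )

    def test_seed_outside_any_object_is_an_error(self, fig5_display):
        _, display, _ = fig5_display
        bad = SeedAnnotation(0, {"male": (70.0, 20.0, 20.0),
                                 "female": (70.0, 95.0, 95.0)})
        with pytest.raises(ValueError, match="seed point"):
            track_sequence([display], bad)
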