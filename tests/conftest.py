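"""Shared fixtures: expensive phantom sessions are built once per run."""

import numpy as np
import pytest

from ocmtrack import (
    ScanProtocol,
    SeedAnnotation,
    make_scenario,
    map_intensity,
    simulate_session,
)

#: reduced phantom geometry that fits a 96**3 field of view
SMALL_CELL = dict(
    grid_shape=(96, 96, 96),
    cell_radius_um=30.0,
    zona_thickness_um=5.0,
    n_lipid_droplets=12,
)

#: reduced grid that still fits the default 40 um cell (fig5 scenarios)
FIG5_GRID = dict(grid_shape=(128, 128, 128))


def one_timepoint_protocol(period_s: float = 30.0, ta_window: int = 10) -> ScanProtocol:
    return ScanProtocol(
        name="unit",
        volume_period_s=period_s,
        ta_window=ta_window,
        session_duration_s=period_s * ta_window,
        volume_duration_s=min(10.0, period_s),
    )


@pytest.fixture(scope="session")
def fig5_timepoint():
    """One 10-look averaged timepoint of the control-zygote scenario."""
    phantom = make_scenario("fig5_control", rng_seed=1)
    volumes, truths = simulate_session(phantom, one_timepoint_protocol())
    return phantom, volumes[0], truths[0]


@pytest.fixture(scope="session")
def fig5_display(fig5_timepoint):
    phantom, volume, truth = fig5_timepoint
    return phantom, map_intensity(volume, "linear"), truth


@pytest.fixture(scope="session")
def division_track():
    """Tracked division scenario (reduced grid, 5-look averaging)."""
    from ocmtrack import track_sequence

    phantom = make_scenario("division", rng_seed=3, **SMALL_CELL)
    protocol = ScanProtocol(
        name="division", volume_period_s=60.0, ta_window=5,
        session_duration_s=3000.0, volume_duration_s=10.0,
    )
    volumes, truths = simulate_session(phantom, protocol)
    display = [map_intensity(v, "linear") for v in volumes]
    table = truths[0].objects
    row = table[table["class"] == "nucleus"].iloc[0]
    seed = SeedAnnotation(0, {"nucleus": (row.cz_um, row.cy_um, row.cx_um)})
    track = track_sequence(display, seed)
    return phantom, volumes, truths, track


def seed_from_truth(truth, frame_index=0):
    table = truth.objects
    nuclear = table[table["class"].isin(["pronucleus", "nucleus"])]
    points = {
        row["tag"]: (row["cz_um"], row["cy_um"], row["cx_um"])
        for _, row in nuclear.iterrows()
    }
    return SeedAnnotation(frame_index, points)
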