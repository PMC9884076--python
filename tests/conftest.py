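import numpy as np
import pytest
from hypothesis import settings

from switchkin.kinetics import ROIGrid, per_roi_kinetics
from switchkin.ratefit import (
    fit_rate_vs_brightness,
    mask_outliers,
    rate_points_from_kinetics,
)
from switchkin.simulate import (
    KineticGroundTruth,
    SimulationConfig,
    make_illumination_map,
    simulate_traces,
)

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

TRUTH = KineticGroundTruth()  # N_tau_on 6000, k_on0 1/300 s⁻¹, beta 2e-5


@pytest.fixture(scope="session")
def gradient_run():
    """One full gradient-illuminated acquisition with per-ROI kinetics."""
    sim = SimulationConfig(n_frames=3000, seed=7)
    illum = make_illumination_map("mems_gradient")
    traces = simulate_traces(sim, illum, TRUTH)
    grid = ROIGrid(7, 7, sim.field_size_um)
    kin = per_roi_kinetics(traces, grid, sim.frame_time_s, sim.n_frames)
    return {"sim": sim, "illum": illum, "truth": TRUTH, "traces": traces,
            "grid": grid, "kin": kin}


@pytest.fixture(scope="session")
def gradient_fits(gradient_run):
    pts = rate_points_from_kinetics(gradient_run["kin"])
    dt = gradient_run["sim"].frame_time_s
    return {
        "off": fit_rate_vs_brightness(mask_outliers(pts, "off"), "off", dt),
        "on": fit_rate_vs_brightness(mask_outliers(pts, "on"), "on", dt),
    }


@pytest.fixture(scope="session")
def flat_run():
    """Flat-field acquisition: every ROI shares the same true kinetics."""
    sim = SimulationConfig(n_frames=2000, seed=11)
    illum = make_illumination_map("flat", peak_kW_cm2=0.48)
    traces = simulate_traces(sim, illum, TRUTH)
    grid = ROIGrid(7, 7, sim.field_size_um)
    kin = per_roi_kinetics(traces, grid, sim.frame_time_s, sim.n_frames)
    return {"sim": sim, "truth": TRUTH, "traces": traces, "grid": grid, "kin": kin}
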