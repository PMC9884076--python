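import io

import numpy as np
import pytest
from scipy import stats

from switchkin.chemistry import BufferCondition, thiolate_fraction
from switchkin.simulate import (
    KineticGroundTruth,
    SimulationConfig,
    localization_table,
    make_illumination_map,
    read_localization_table,
    simulate_acidification_series,
    simulate_traces,
    write_localization_table,
)


class TestIllumination:
    def test_flat_constant(self):
        m = make_illumination_map("flat", peak_kW_cm2=0.72)
        assert np.all(m.intensity_kW_cm2 == 0.72)
        assert m.intensity_at(1.0, 60.0) == pytest.approx(0.72)

    def test_gradient_corner_value(self):
        m = make_illumination_map("mems_gradient", 0.48, edge_fraction=0.2)
        assert m.intensity_at(31.25, 31.25) == pytest.approx(0.48)
        assert m.intensity_at(0.0, 0.0) == pytest.approx(0.48 * 0.2)
        assert m.intensity_at(62.5, 62.5) == pytest.approx(0.48 * 0.2)

    def test_gradient_block_means_decrease_outward(self):
        """7x7 block means fall monotonically from the centre along axes."""
        m = make_illumination_map("mems_gradient", grid_shape=(49, 49))
        blocks = m.intensity_kW_cm2.reshape(7, 7, 7, 7).mean(axis=(1, 3))
        centre_row = blocks[3]
        assert np.all(np.diff(centre_row[:4]) > 0)
        assert np.all(np.diff(centre_row[3:]) < 0)
        col = blocks[:, 3]
        assert np.all(np.diff(col[:4]) > 0)
        assert np.all(np.diff(col[3:]) < 0)

    def test_positive_everywhere_and_interior_max(self):
        m = make_illumination_map("mems_gradient")
        assert np.all(m.intensity_kW_cm2 > 0)
        i, j = np.unravel_index(np.argmax(m.intensity_kW_cm2), m.grid_shape)
        assert 0 < i < m.grid_shape[0] - 1 and 0 < j < m.grid_shape[1] - 1

    def test_invalid_mode(self):
        with pytest.raises(ValueError):
            make_illumination_map("vortex")
        with pytest.raises(ValueError):
            make_illumination_map("mems_gradient", edge_fraction=1.5)


def _small_sim(**kw):
    base = dict(n_frames=2000, field_size_um=20.0, density_per_um2=3.0, seed=5)
    base.update(kw)
    return SimulationConfig(**base)


class TestBlinkingModel:
    def test_seeded_determinism(self):
        cfg = _small_sim()
        illum = make_illumination_map(field_size_um=cfg.field_size_um)
        truth = KineticGroundTruth()
        t1 = localization_table(simulate_traces(cfg, illum, truth))
        t2 = localization_table(simulate_traces(cfg, illum, truth))
        b1, b2 = io.StringIO(), io.StringIO()
        t1.to_csv(b1, index=False)
        t2.to_csv(b2, index=False)
        assert b1.getvalue() == b2.getvalue()

    def test_on_dwells_exponential(self):
        """KS test cannot reject Exp(k_off) for >= 1e4 simulated on dwells."""
        truth = KineticGroundTruth(k_on0_per_s=0.2)  # fast recovery: many events
        cfg = _small_sim(n_frames=4000)
        illum = make_illumination_map("flat", 0.48, field_size_um=cfg.field_size_um)
        traces = simulate_traces(cfg, illum, truth)
        dwells = np.concatenate([t.true_dwells_on for t in traces])
        assert dwells.size >= 10_000
        R = truth.brightness_coeff * 0.48
        k_off = R / (truth.N_tau_on * cfg.frame_time_s)
        p = stats.kstest(dwells, stats.expon(scale=1.0 / k_off).cdf).pvalue
        assert p > 0.01

    def test_on_dwell_halves_when_brightness_doubles(self):
        cfg = _small_sim()
        means = []
        for coeff in (800.0, 1600.0):
            truth = KineticGroundTruth(brightness_coeff=coeff, k_on0_per_s=0.2)
            illum = make_illumination_map("flat", 0.48, field_size_um=cfg.field_size_um)
            traces = simulate_traces(cfg, illum, truth)
            d = np.concatenate([t.true_dwells_on for t in traces])
            assert d.size >= 10_000
            means.append(d.mean())
        assert means[0] / means[1] == pytest.approx(2.0, rel=0.05)

    def test_photon_budget_matches_truth(self):
        """Mean photons per completed on-event ~ N_tau_on within 5%."""
        truth = KineticGroundTruth(N_tau_on=6000.0, k_on0_per_s=0.2)
        cfg = _small_sim(n_frames=4000)
        illum = make_illumination_map("flat", 0.48, field_size_um=cfg.field_size_um)
        traces = simulate_traces(cfg, illum, truth)
        tot = 0.0
        n_ev = 0
        T = cfg.n_frames * cfg.frame_time_s
        for tr in traces:
            if tr.on_intervals_s.size and tr.on_intervals_s[-1, 1] < T - 1e-9:
                tot += tr.total_photons
                n_ev += tr.on_intervals_s.shape[0]
        assert n_ev >= 10_000
        assert tot / n_ev == pytest.approx(6000.0, rel=0.05)

    def test_thermal_only_recovery_position_independent(self):
        """With beta_on = 0 the off dwell mean is 1/k_on0 everywhere."""
        truth = KineticGroundTruth(k_on0_per_s=0.25, beta_on=0.0)
        cfg = _small_sim(n_frames=4000)
        illum = make_illumination_map(
            "mems_gradient", 0.48, field_size_um=cfg.field_size_um
        )
        traces = simulate_traces(cfg, illum, truth)
        c = cfg.field_size_um / 2
        inner, outer = [], []
        for tr in traces:
            r = np.hypot(tr.position_um[0] - c, tr.position_um[1] - c)
            (inner if r < c / 2 else outer).append(tr.true_dwells_off)
        d_in = np.concatenate(inner)
        d_out = np.concatenate(outer)
        assert d_in.mean() == pytest.approx(4.0, rel=0.1)
        assert d_out.mean() == pytest.approx(4.0, rel=0.1)

    def test_brightness_linear_in_intensity(self, gradient_run):
        """Median on-frame photons scale linearly with local intensity."""
        traces = [t for t in gradient_run["traces"] if t.frames.size >= 5]
        illum = gradient_run["illum"]
        I = np.array([illum.intensity_at(*t.position_um) for t in traces])
        med = np.array([np.median(t.photons) for t in traces])
        edges = np.quantile(I, np.linspace(0, 1, 50))
        idx = np.clip(np.searchsorted(edges, I) - 1, 0, 48)
        x = np.array([I[idx == b].mean() for b in range(49)])
        y = np.array([np.median(med[idx == b]) for b in range(49)])
        r = np.corrcoef(x, y)[0, 1]
        assert r**2 > 0.99

    def test_photon_conservation_per_trace(self):
        cfg = _small_sim(n_frames=500)
        traces = simulate_traces(
            cfg, make_illumination_map(field_size_um=cfg.field_size_um),
            KineticGroundTruth(),
        )
        tr = next(t for t in traces if t.frames.size)
        assert tr.frame_photons.sum() == pytest.approx(tr.photons.sum())
        assert tr.frame_photons.size == cfg.n_frames

    def test_invalid_configs(self):
        with pytest.raises(ValueError):
            SimulationConfig(field_size_um=0.0)
        with pytest.raises(ValueError):
            SimulationConfig(n_frames=0)
        with pytest.raises(ValueError):
            KineticGroundTruth(N_tau_on=-1.0)


class TestLocalizationTable:
    def test_threshold_and_all_off(self):
        cfg = _small_sim(n_frames=300)
        traces = simulate_traces(
            cfg, make_illumination_map(field_size_um=cfg.field_size_um),
            KineticGroundTruth(),
        )
        tab = localization_table(traces, min_photons_threshold=0.0)
        n_pairs = sum(t.frames.size for t in traces)
        assert len(tab) == n_pairs
        # molecules with no detections contribute no rows
        n_silent = sum(1 for t in traces if t.frames.size == 0)
        assert n_silent > 0
        assert tab["frame"].min() >= 1

    def test_roundtrip(self, tmp_path):
        cfg = _small_sim(n_frames=300)
        traces = simulate_traces(
            cfg, make_illumination_map(field_size_um=cfg.field_size_um),
            KineticGroundTruth(),
        )
        path = tmp_path / "locs.csv"
        write_localization_table(localization_table(traces), path)
        back = read_localization_table(path)
        first = localization_table(traces)
        assert np.array_equal(back["frame"], first["frame"])
        assert np.allclose(back["photons"], first["photons"])
        assert np.allclose(back["x_nm"], first["x_nm"], atol=1e-3)


class TestAcidification:
    CAL = {0.1: (300.0, 20.0), 1.0: (250.0, 60.0), 3.0: (200.0, 120.0),
           5.0: (161.0, 169.0)}

    def test_zero_drift_constant(self):
        buf = BufferCondition(50.0, 7.4)
        out = simulate_acidification_series(buf, 0.0, [0, 2, 4], self.CAL)
        assert out["tau_on_ms"].nunique() == 1
        assert out["tau_off_s"].nunique() == 1

    def test_thiolate_falls_by_fraction_ratio(self):
        buf = BufferCondition(50.0, 7.4)
        out = simulate_acidification_series(buf, 0.5, [0, 2], self.CAL)
        expected = thiolate_fraction(7.4, 8.353) / thiolate_fraction(6.4, 8.353)
        assert out["thiolate_mM"][0] / out["thiolate_mM"][1] == pytest.approx(expected)

    def test_monotone_kinetics_under_drift(self):
        buf = BufferCondition(50.0, 7.4)
        out = simulate_acidification_series(buf, 0.5, [0, 1, 2, 3, 4], self.CAL)
        assert np.all(np.diff(out["tau_off_s"]) < 0)
        assert np.all(np.diff(out["tau_on_ms"]) >= 0)

    def test_empty_calibration_rejected(self):
        with pytest.raises(ValueError):
            simulate_acidification_series(BufferCondition(50, 7.4), 0.5, [0], {})
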