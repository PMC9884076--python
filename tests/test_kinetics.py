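import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from switchkin.kinetics import (
    DwellTimes,
    ROIGrid,
    assign_rois,
    estimate_tau,
    extract_dwells,
    link_traces,
    per_roi_kinetics,
    relative_change,
)


def brute_force_dwells(occupancy, max_gap=0):
    """Independent run-length oracle: frame-by-frame scan with gap bridging."""
    n = len(occupancy)
    frames = [i + 1 for i, v in enumerate(occupancy) if v]
    if not frames:
        return [], [], [], 0, 0
    runs = [[frames[0], frames[0]]]
    for f in frames[1:]:
        if f - runs[-1][1] <= max_gap + 1:
            runs[-1][1] = f
        else:
            runs.append([f, f])
    on, censored, off = [], [], []
    for k, (a, b) in enumerate(runs):
        ln = b - a + 1
        if a == 1 or b == n:
            censored.append(ln)
        else:
            on.append(ln)
        if k:
            off.append(a - runs[k - 1][1] - 1)
    return on, off, censored, runs[0][0] - 1, n - runs[-1][1]


class TestROIGrid:
    def test_center_and_origin(self):
        g = ROIGrid(7, 7, 62.5)
        assert g.roi_index(31.25, 31.25) == g.center_roi_id
        assert g.roi_xy(np.array([g.center_roi_id])) == (3, 3)
        assert g.roi_index(0.0, 0.0) == 0
        assert g.roi_index(62.5, 62.5) == 48  # top edge inclusive

    def test_out_of_bounds_reports_rows(self):
        g = ROIGrid(7, 7, 62.5)
        with pytest.raises(ValueError, match="rows"):
            g.roi_index(np.array([1.0, 70.0]), np.array([1.0, 1.0]))

    def test_uniform_occupancy(self):
        rng = np.random.default_rng(0)
        n = 49_000
        g = ROIGrid(7, 7, 62.5)
        table = pd.DataFrame(
            {
                "frame": np.ones(n, dtype=int),
                "x_nm": rng.uniform(0, 62500, n),
                "y_nm": rng.uniform(0, 62500, n),
                "photons": np.ones(n),
            }
        )
        out = assign_rois(table, g)
        counts = out["roi_id"].value_counts()
        assert len(out) == n  # grid conservation
        exp = n / 49
        sigma = np.sqrt(n * (1 / 49) * (48 / 49))
        assert np.all(np.abs(counts - exp) < 3 * sigma + 1)


class TestExtractDwells:
    def test_gap_bridging_examples(self):
        dw = extract_dwells(np.array([10, 11, 12, 14]), 100, max_gap_frames=1)
        assert list(dw.on_dwells_frames) == [5]
        assert list(dw.off_dwells_frames) == []
        dw0 = extract_dwells(np.array([10, 11, 12, 14]), 100, max_gap_frames=0)
        assert list(dw0.on_dwells_frames) == [3, 1]
        assert list(dw0.off_dwells_frames) == [1]

    def test_all_on_trace_censored(self):
        dw = extract_dwells(np.ones(20, dtype=bool), 20)
        assert dw.on_dwells_frames.size == 0
        assert list(dw.censored_on_frames) == [20]
        assert dw.off_dwells_frames.size == 0

    def test_alternating(self):
        occ = np.zeros(21, dtype=bool)
        occ[1::2] = True  # frames 2,4,...,20
        dw = extract_dwells(occ, 21)
        assert np.all(dw.on_dwells_frames == 1)
        assert np.all(dw.off_dwells_frames == 1)

    def test_empty(self):
        dw = extract_dwells(np.array([], dtype=int), 50)
        assert dw.empty

    @given(
        bits=st.lists(st.booleans(), min_size=1, max_size=200),
        gap=st.integers(min_value=0, max_value=3),
    )
    def test_matches_brute_force_oracle(self, bits, gap):
        """Run-length extraction equals an independent frame-scan oracle."""
        occ = np.array(bits)
        dw = extract_dwells(occ, occ.size, max_gap_frames=gap)
        on, off, cens, lead, trail = brute_force_dwells(bits, gap)
        assert list(dw.on_dwells_frames) == on
        assert list(dw.off_dwells_frames) == off
        assert list(dw.censored_on_frames) == cens
        if occ.any():
            assert dw.leading_off_frames == lead
            assert dw.trailing_off_frames == trail


class TestEstimateTau:
    def test_exact_mean(self):
        est = estimate_tau([4] * 12, 0.05)
        assert est.tau_s == pytest.approx(0.2)
        assert est.se_s == pytest.approx(0.2 / np.sqrt(12))
        assert est.valid

    def test_too_few_events_flagged(self):
        est = estimate_tau([], 0.05)
        assert not est.valid and np.isnan(est.tau_s)
        est = estimate_tau([3, 4], 0.05, min_events=10)
        assert not est.valid

    def test_recovers_exponential_scale(self):
        rng = np.random.default_rng(1)
        d = rng.exponential(3.22, 10_000)
        frames = np.floor(rng.uniform(0, 1, d.size) + d).astype(int) + 1
        est = estimate_tau(frames, 0.05, correction_frames=-1.0)
        assert abs(est.tau_s - 0.161) < 3 * est.se_s

    def test_expfit_agrees_with_mean(self):
        rng = np.random.default_rng(2)
        frames = np.ceil(rng.exponential(6.0, 20_000)).astype(int)
        m = estimate_tau(frames, 0.05, "mean")
        e = estimate_tau(frames, 0.05, "expfit")
        assert abs(m.tau_s - e.tau_s) < m.se_s + e.se_s

    def test_consistency_over_replicates(self):
        """Mean estimator hits the true lifetime within 3 SE >= 99% of runs."""
        rng = np.random.default_rng(3)
        hits = 0
        reps = 1000
        for _ in range(reps):
            d = rng.exponential(5.0, 200)
            frames = np.floor(rng.uniform(0, 1, d.size) + d).astype(int) + 1
            est = estimate_tau(frames, 1.0, correction_frames=-1.0)
            hits += abs(est.tau_s - 5.0) <= 3 * est.se_s
        assert hits / reps >= 0.99


class TestLinking:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["frame", "x_nm", "y_nm", "photons"])

    def test_single_molecule_consecutive(self):
        rows = [(f, 1000.0, 1000.0, 500.0) for f in range(5, 9)]
        tr = link_traces(self._table(rows), n_frames=100)
        assert len(tr) == 1
        assert list(tr[0].frames) == [5, 6, 7, 8]

    def test_two_distant_molecules(self):
        rows = [(1, 1000.0, 1000.0, 500.0), (1, 9000.0, 9000.0, 400.0),
                (2, 1010.0, 995.0, 480.0)]
        tr = link_traces(self._table(rows), n_frames=10)
        assert len(tr) == 2
        by_id = {t.molecule_id: t for t in tr}
        assert by_id[0].frames.size == 2

    def test_nearest_assignment(self):
        rows = [(1, 0.0, 0.0, 100.0), (1, 300.0, 0.0, 100.0),
                (2, 90.0, 0.0, 100.0)]
        tr = link_traces(self._table(rows), n_frames=10, link_radius_nm=250)
        by_id = {t.molecule_id: t for t in tr}
        assert by_id[0].frames.size == 2  # joined the closer trace


class TestPerRoiKinetics:
    def test_ratio_and_duty_cycle_identities(self, gradient_run):
        kin = gradient_run["kin"]
        ok = kin[kin["valid"]]
        assert len(ok) == 49
        np.testing.assert_allclose(
            ok["ratio"], ok["tau_off_s"] / (ok["tau_on_ms"] / 1e3), rtol=1e-9
        )
        np.testing.assert_allclose(
            ok["ratio"], (1 - ok["duty_cycle"]) / ok["duty_cycle"], rtol=1e-9
        )
        np.testing.assert_allclose(ok["k_off_per_s"], 1e3 / ok["tau_on_ms"], rtol=1e-9)

    def test_central_roi_fastest_off_switching(self, gradient_run):
        """Peak intensity at the FOV centre gives the smallest tau_on."""
        kin = gradient_run["kin"]
        centre = gradient_run["grid"].center_roi_id
        assert kin.loc[kin["roi_id"] == centre, "tau_on_ms"].iloc[0] == kin["tau_on_ms"].min()
        # and the brightest spots
        assert kin.loc[kin["roi_id"] == centre, "n_det_photons"].iloc[0] == kin["n_det_photons"].max()

    def test_flat_illumination_homogeneous(self, flat_run):
        kin = flat_run["kin"]
        ok = kin[kin["valid"]]
        grand = ok["tau_on_ms"].mean()
        z = (ok["tau_on_ms"] - grand) / ok["tau_on_se_ms"]
        assert np.all(np.abs(z) < 3.5)

    def test_empty_roi_flagged_invalid(self):
        grid = ROIGrid(2, 2, 10.0)

        class T:
            position_um = (1.0, 1.0)
            frames = np.arange(10, 20)
            photons = np.full(10, 400.0)
            n_frames = 100

        kin = per_roi_kinetics([T()], grid, 0.05, 100, min_events=1)
        assert not kin.loc[kin["roi_id"] == 3, "valid"].iloc[0]


class TestRelativeChange:
    def test_acidification_percentages(self):
        out = relative_change([161.0, 183.0, 224.0])
        assert round(out[2]) == 39
        out_off = relative_change([169.0, 97.0, 55.0])
        assert round(out_off[2], 1) == -67.5
        assert relative_change([5.0, 5.0])[1] == 0.0

    def test_zero_baseline(self):
        with pytest.raises(ValueError):
            relative_change([0.0, 1.0])
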