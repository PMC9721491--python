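"""Windowed slopes, engagement detection, path geometry, binned averages."""

import numpy as np
import pytest

from fatecommit import (
    CellTrace,
    SimConfig,
    TimeGrid,
    TrajectorySet,
    bin_and_average,
    canonical_trace,
    detect_engagement,
    fold_change,
    population_mean_slope,
    simulate_population,
    sliding_window_slope,
    unit_square_normalize,
)


def _trace(values, cell_id="x", grid=None, channel="PPARG"):
    g = grid or TimeGrid(0, 0.2, len(values))
    return CellTrace(cell_id, "c", g.times(), {channel: np.asarray(values, float)})


def _normalized_canonical():
    tr = canonical_trace()
    n = (tr.values("PPARG") / 100.0 - 1.0) / 7.0
    return CellTrace("canon", "control", tr.times, {"PPARG": n})


class TestSlidingWindowSlope:
    def test_exact_line(self):
        t = TimeGrid(0, 0.2, 100).times()
        ss = sliding_window_slope(_trace(3.0 + 0.5 * t))
        np.testing.assert_allclose(ss.slopes[ss.valid], 0.5, rtol=1e-9)

    def test_constant_trace(self):
        ss = sliding_window_slope(_trace(np.full(60, 7.0)))
        np.testing.assert_allclose(ss.slopes[ss.valid], 0.0, atol=1e-9)

    def test_canonical_segment_slope(self):
        # window centered at 22 h lies fully inside the second-phase segment
        ss = sliding_window_slope(_normalized_canonical())
        i = np.argmin(np.abs(ss.times - 22.0))
        assert ss.slopes[i] == pytest.approx(0.0080, rel=1e-9)

    def test_matches_polyfit_oracle(self):
        rng = np.random.default_rng(0)
        t = TimeGrid(0, 0.2, 120).times()
        y = rng.random(120)
        tr = _trace(y)
        ss = sliding_window_slope(tr)
        for i in (0, 30, 60, 119):
            w = (t >= t[i] - 4.0) & (t <= t[i] + 4.0)
            expect = np.polyfit(t[w], y[w], 1)[0]
            assert ss.slopes[i] == pytest.approx(expect, rel=1e-9, abs=1e-12)

    def test_too_short_trace(self):
        with pytest.raises(ValueError):
            sliding_window_slope(_trace([1, 2, 3]))

    def test_missing_channel(self):
        with pytest.raises(KeyError):
            sliding_window_slope(_trace([1] * 50), channel="FABP4")


class TestPopulationMeanSlope:
    def test_single_cell_equals_own_series(self):
        tr = _normalized_canonical()
        ts = TrajectorySet(TimeGrid(), [tr])
        mean = population_mean_slope(ts, fates={"canon": "differentiated"})
        own = sliding_window_slope(tr)
        np.testing.assert_allclose(
            mean["differentiated"].slopes[own.valid], own.slopes[own.valid], rtol=1e-12)

    def test_two_identical_cells(self):
        a = _normalized_canonical()
        b = CellTrace("b", "control", a.times, dict(a.channels))
        ts = TrajectorySet(TimeGrid(), [a, b])
        mean = population_mean_slope(ts)["all"]
        own = sliding_window_slope(a)
        np.testing.assert_allclose(mean.slopes[own.valid], own.slopes[own.valid], rtol=1e-12)

    def test_late_slope_exceeds_early_for_differentiated(self, default_pop):
        fates = {c: t.fate for c, t in default_pop.truth.items()}
        mean = population_mean_slope(default_pop, fates=fates)["differentiated"]
        at = lambda h: mean.slopes[np.argmin(np.abs(mean.times - h))]
        assert at(34.0) >= 3.0 * at(10.0)


class TestDetectEngagement:
    def test_constant_slope_none(self):
        t = TimeGrid(0, 0.2, 481).times()
        ss = sliding_window_slope(_trace(1.0 + 0.01 * t))
        assert detect_engagement(ss) is None

    def test_canonical_engagement_near_cebpa_point(self):
        # windowed OLS first sustains 2x the Phase-1 slope ~1.5-3 h after tau_A
        ss = sliding_window_slope(_normalized_canonical())
        e = detect_engagement(ss)
        assert e is not None and 17.0 <= e <= 21.0

    def test_arrested_knockdown_never_engages(self):
        cfg = SimConfig(n_cells=2, seed=0, scenario="siCEBPA", p_diff=1.0,
                        p_escape_siCEBPA=0.0, sigma_m=0.0, sigma_t=0.0,
                        slope_cv=0.0, p_dropout=0.0, p_late_start=0.0, p_spike=0.0)
        ts = simulate_population(cfg)
        ss = sliding_window_slope(ts.traces[0])
        assert detect_engagement(ss) is None

    def test_noisy_population_median_in_phase2(self):
        meds = []
        for seed in range(5):
            ts = simulate_population(SimConfig(n_cells=100, seed=seed))
            est = []
            for tr in ts.traces:
                if (ts.truth[tr.cell_id].fate == "differentiated"
                        and tr.times[0] < 1.0 and tr.times[-1] > 90.0):
                    e = detect_engagement(sliding_window_slope(tr))
                    if e is not None:
                        est.append(e)
            meds.append(np.median(est))
        assert 17.0 <= np.median(meds) <= 27.0

    def test_negative_baseline_needs_floor(self):
        t = TimeGrid(0, 0.2, 481).times()
        ss = sliding_window_slope(_trace(100.0 - 0.5 * t))
        with pytest.raises(ValueError, match="floor"):
            detect_engagement(ss)


class TestUnitSquarePaths:
    def _ts(self, xy_by_cell):
        g = None
        traces = []
        for cid, (x, y) in xy_by_cell.items():
            g = TimeGrid(0, 0.2, len(x))
            traces.append(CellTrace(cid, "c", g.times(),
                                    {"PPARG": np.asarray(x, float),
                                     "FABP4": np.asarray(y, float)}))
        return TrajectorySet(g, traces)

    def test_diagonal_path_zero_asymmetry(self):
        u = np.linspace(0, 1, 50)
        ps = unit_square_normalize(self._ts({"d": (u, u)}))
        assert ps.asymmetry == pytest.approx(0.0, abs=1e-9)

    def test_l_shaped_path_half_area(self):
        x = np.concatenate([np.linspace(0, 1, 50), np.full(50, 1.0)])
        y = np.concatenate([np.zeros(50), np.linspace(0, 1, 50)])
        ps = unit_square_normalize(self._ts({"L": (x, y)}))
        assert ps.asymmetry == pytest.approx(0.5, abs=1e-6)
        # mirrored path (y first) gives the opposite sign
        ps2 = unit_square_normalize(self._ts({"L": (y, x)}))
        assert ps2.asymmetry == pytest.approx(-0.5, abs=1e-6)

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        x = np.cumsum(rng.random(80))
        y = np.cumsum(rng.random(80))
        a = unit_square_normalize(self._ts({"c": (x, y)}))
        b = unit_square_normalize(self._ts({"c": (5.0 * x + 40.0, 0.3 * y + 7.0)}))
        np.testing.assert_allclose(a.mean_path, b.mean_path, atol=1e-12)

    def test_constant_channel_skipped(self):
        u = np.linspace(0, 1, 30)
        with pytest.warns(UserWarning, match="constant"):
            ps = unit_square_normalize(self._ts({"ok": (u, u), "flat": (u, 0 * u)}))
        assert ps.skipped == ["flat"]

    def test_differentiated_cells_pparg_leads(self, clean_pop):
        diff = [c for c, t in clean_pop.truth.items() if t.fate == "differentiated"]
        ps = unit_square_normalize(clean_pop, cells=diff)
        assert ps.asymmetry > 0.1


class TestBinAndAverage:
    def _pop(self, n=8, seed=0):
        return simulate_population(SimConfig(
            n_cells=n, seed=seed, p_dropout=0.0, p_late_start=0.0, p_spike=0.0))

    def test_four_cells_four_bins(self):
        ts = self._pop(4)
        binned = bin_and_average(ts, n_bins=4)
        assert sorted(binned.bin_of.values()) == [0, 1, 2, 3]
        for tr in ts.traces:
            b = binned.bin_of[tr.cell_id]
            np.testing.assert_allclose(binned.mean_traces["PPARG"][b], tr.values("PPARG"))

    def test_identical_cells_identical_bins(self):
        g = TimeGrid(0, 0.2, 481)
        v = np.linspace(1, 10, 481)
        traces = [CellTrace(f"c{i}", "c", g.times(), {"PPARG": v.copy()})
                  for i in range(8)]
        binned = bin_and_average(TrajectorySet(g, traces), n_bins=4)
        for b in range(4):
            np.testing.assert_allclose(binned.mean_traces["PPARG"][b], v)

    def test_partition_disjoint_exhaustive(self):
        ts = self._pop(40, seed=2)
        binned = bin_and_average(ts, n_bins=4)
        assert set(binned.bin_of) == {tr.cell_id for tr in ts.traces}
        counts = np.bincount(list(binned.bin_of.values()), minlength=4)
        assert counts.sum() == 40 and counts.max() - counts.min() <= 1

    def test_top_bin_fabp4_dwarfs_bottom_bin(self):
        ts = self._pop(200, seed=3)
        binned = bin_and_average(ts, n_bins=4)
        F = binned.mean_traces["FABP4"]
        assert F[3, -1] >= 10.0 * F[0, -1]

    def test_incomplete_trace_rejected(self, default_pop):
        with pytest.raises(ValueError, match="cover"):
            bin_and_average(default_pop, n_bins=4)


class TestFoldChange:
    def test_constant_trace(self):
        assert fold_change(_trace(np.full(10, 4.0))) == 1.0

    def test_canonical_values(self, canonical):
        assert fold_change(canonical, "PPARG") == pytest.approx(7.954, abs=0.001)
        assert fold_change(canonical, "FABP4") == pytest.approx(447.2, rel=1e-3)

    def test_nonpositive_min_errors(self):
        with pytest.raises(ValueError):
            fold_change(_trace([0.0, 1.0, 2.0, 3.0, 4.0]))
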