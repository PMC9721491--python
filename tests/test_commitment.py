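"""Mixture fate calls, threshold scan (vs brute-force oracle), hit times."""

import numpy as np
import pytest

from fatecommit import (
    SimConfig,
    TimeGrid,
    TrajectorySet,
    CellTrace,
    apply_qc,
    canonical_trace,
    classify_fate,
    fit_endpoint_mixture,
    histogram_midpoint_threshold,
    percent_differentiated,
    select_threshold,
    simulate_population,
    threshold_hit_times,
    transfer_threshold,
)
from fatecommit.commitment import DegenerateInputError, InsufficientDataError


def _bimodal(n=500, lo=1.0, hi=8.0, spread=0.03, seed=0):
    rng = np.random.default_rng(seed)
    return np.concatenate([
        lo * np.exp(rng.normal(0, spread, n)),
        hi * np.exp(rng.normal(0, spread, n)),
    ])


class TestMixture:
    def test_separated_clusters_recovered(self):
        v = _bimodal()
        fit = fit_endpoint_mixture(v)
        assert fit.means[0] == pytest.approx(np.log10(1.0), abs=0.02)
        assert fit.means[1] == pytest.approx(np.log10(8.0), abs=0.02)
        np.testing.assert_allclose(fit.weights, [0.5, 0.5], atol=0.02)
        assert not fit.degenerate

    def test_unimodal_flagged_degenerate(self):
        rng = np.random.default_rng(1)
        v = 5.0 * np.exp(rng.normal(0, 0.1, 400))
        fit = fit_endpoint_mixture(v)
        assert fit.degenerate
        with pytest.raises(DegenerateInputError):
            classify_fate(fit, v)

    def test_too_few_values(self):
        with pytest.raises(InsufficientDataError):
            fit_endpoint_mixture([1.0, 2.0, 3.0, 4.0, 5.0])

    def test_zero_variance(self):
        with pytest.raises(DegenerateInputError):
            fit_endpoint_mixture(np.full(20, 3.0))

    def test_component_means_classified_to_own_side(self):
        fit = fit_endpoint_mixture(_bimodal())
        labels = classify_fate(fit, np.array([1.0, 8.0]))
        assert labels == ["undifferentiated", "differentiated"]

    def test_classification_matches_truth_on_simulated_endpoint(self):
        ts = simulate_population(SimConfig(n_cells=1000, seed=6))
        kept, _ = apply_qc(ts)
        snap = kept.endpoint_values("PPARG")
        fit = fit_endpoint_mixture(snap)
        labels = classify_fate(fit, snap)
        truth = [ts.truth[c].fate for c in snap.cell_ids]
        acc = np.mean([a == b for a, b in zip(labels, truth)])
        assert acc >= 0.95


def brute_force_threshold(values, fates, fpr_max, rule):
    """Independent exhaustive scan implementing the documented selection rule."""
    sv = sorted(set(values))
    cands = [sv[0]] + [(a + b) / 2 for a, b in zip(sv[:-1], sv[1:])] + [sv[-1]]
    pos = [v for v, f in zip(values, fates) if f == "differentiated"]
    neg = [v for v, f in zip(values, fates) if f == "undifferentiated"]
    scored = []
    for c in cands:
        fpr = sum(v >= c for v in neg) / len(neg)
        tpr = sum(v >= c for v in pos) / len(pos)
        if fpr < fpr_max:
            scored.append((c, fpr, tpr))
    if not scored:
        return None
    if rule == "min_feasible":
        return scored[0][0]
    best_tpr = max(s[2] for s in scored)
    scored = [s for s in scored if s[2] == best_tpr]
    best_fpr = min(s[1] for s in scored)
    scored = [s for s in scored if s[1] == best_fpr]
    return scored[len(scored) // 2][0]


class TestSelectThreshold:
    def test_separable_populations(self):
        v = np.array([1.0, 1.5, 2.0, 5.0, 6.0, 8.0])
        f = ["undifferentiated"] * 3 + ["differentiated"] * 3
        model = select_threshold(v, f)
        assert 2.0 < model.threshold <= 5.0
        assert model.fpr == 0.0 and model.tpr == 1.0

    @pytest.mark.parametrize("rule", ["max_margin", "min_feasible"])
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_brute_force_oracle(self, rule, seed):
        rng = np.random.default_rng(seed)
        n = 120
        v = np.concatenate([rng.normal(3, 1.2, n), rng.normal(6, 1.5, n)]).clip(0.1)
        f = ["undifferentiated"] * n + ["differentiated"] * n
        model = select_threshold(v, f, fpr_max=0.05, rule=rule)
        expect = brute_force_threshold(list(v), f, 0.05, rule)
        assert model.threshold == pytest.approx(expect, rel=1e-12)
        assert model.fpr < 0.05

    def test_min_feasible_maximizes_tpr(self):
        rng = np.random.default_rng(7)
        v = np.concatenate([rng.normal(3, 1, 100), rng.normal(5, 1, 100)]).clip(0.1)
        f = ["undifferentiated"] * 100 + ["differentiated"] * 100
        model = select_threshold(v, f, rule="min_feasible")
        pos = v[100:]
        for c in model.candidates:
            fpr = np.mean(v[:100] >= c)
            if fpr < 0.05:
                assert model.tpr >= np.mean(pos >= c)

    def test_unconstrained_limit_min_feasible(self):
        v = np.array([1.0, 2.0, 5.0, 6.0])
        f = ["undifferentiated", "undifferentiated", "differentiated", "differentiated"]
        model = select_threshold(v, f, fpr_max=1.0, rule="min_feasible")
        # smallest candidate with FPR strictly below 1.0: the first midpoint
        assert model.threshold == pytest.approx(1.5)
        assert model.tpr == 1.0

    @pytest.mark.parametrize("rule", ["max_margin", "min_feasible"])
    def test_raising_fpr_max_never_raises_threshold(self, rule):
        rng = np.random.default_rng(11)
        v = np.concatenate([rng.normal(3, 1, 200), rng.normal(6, 1, 200)]).clip(0.1)
        f = ["undifferentiated"] * 200 + ["differentiated"] * 200
        prev = np.inf
        for fpr_max in (0.01, 0.05, 0.10, 0.30, 1.0):
            thr = select_threshold(v, f, fpr_max=fpr_max, rule=rule).threshold
            assert thr <= prev + 1e-12
            prev = thr

    def test_one_class_absent_errors(self):
        with pytest.raises(ValueError, match="both fate classes"):
            select_threshold([1.0, 2.0], ["differentiated", "differentiated"])

    def test_infeasible_constraint_flagged(self):
        # perfectly interleaved values: every candidate has FPR >= 0.5 or TPR 0
        v = [1.0, 1.0, 2.0, 2.0]
        f = ["undifferentiated", "differentiated"] * 2
        with pytest.warns(UserWarning):
            model = select_threshold(v, f, fpr_max=0.01)
        assert not model.constraint_met


class TestTransferAndPercent:
    def test_transfer_identical_values_identical_calls(self):
        v = _bimodal(seed=3)
        fit = fit_endpoint_mixture(v)
        fates = classify_fate(fit, v)
        model = select_threshold(v, fates)
        assert transfer_threshold(fit, model, v) == model.labels

    def test_transfer_all_below(self):
        v = _bimodal(seed=4)
        fit = fit_endpoint_mixture(v)
        model = select_threshold(v, classify_fate(fit, v))
        calls = transfer_threshold(fit, model, np.full(50, 0.01))
        assert all(c == "undifferentiated" for c in calls)

    def test_transfer_sifabp4_recovers_escape_fraction(self):
        ctrl = simulate_population(SimConfig(n_cells=1000, seed=5))
        kept, _ = apply_qc(ctrl)
        snap = kept.endpoint_values("PPARG")
        fit = fit_endpoint_mixture(snap)
        fates = classify_fate(fit, snap)
        vals48, ids = kept.values_at(48.0, "PPARG")
        fmap = dict(zip(snap.cell_ids, fates))
        model = select_threshold(vals48, [fmap[c] for c in ids])
        kd = simulate_population(SimConfig(n_cells=1000, seed=6, scenario="siFABP4"))
        kd_kept, _ = apply_qc(kd)
        calls = transfer_threshold(fit, model, kd_kept.endpoint_values("PPARG"))
        frac = np.mean([c == "differentiated" for c in calls])
        assert frac == pytest.approx(0.10, abs=0.03)

    def test_histogram_midpoint_closed_form(self):
        # tight peaks at 1 and 9: geometric midpoint 10**((0+0.954)/2) = 3
        v = _bimodal(lo=1.0, hi=9.0, spread=0.01, seed=8)
        assert histogram_midpoint_threshold(v) == pytest.approx(3.0, rel=0.02)

    def test_histogram_midpoint_scale_equivariant(self):
        v = _bimodal(seed=9)
        t1 = histogram_midpoint_threshold(v)
        t2 = histogram_midpoint_threshold(v * 7.5)
        assert t2 == pytest.approx(7.5 * t1, rel=1e-6)

    def test_histogram_midpoint_unimodal_errors(self):
        rng = np.random.default_rng(10)
        with pytest.raises(DegenerateInputError):
            histogram_midpoint_threshold(4.0 * np.exp(rng.normal(0, 0.05, 300)))

    def test_percent_differentiated_examples(self):
        assert percent_differentiated([1, 2, 6, 8], 4.0) == 0.5
        assert percent_differentiated([1, 2, 6, 8], 9.0) == 0.0
        assert percent_differentiated([1, 2, 6, 8], 6.0) == 0.5  # tie counts above
        with pytest.raises(InsufficientDataError):
            percent_differentiated([], 1.0)

    def test_scale_invariance_of_calls(self):
        rng = np.random.default_rng(12)
        v = rng.uniform(1, 10, 200)
        thr = 4.2
        base = percent_differentiated(v, thr)
        assert percent_differentiated(v * 3.7, thr * 3.7) == base

    def test_percent_on_control_at_96h_recovers_p_diff(self):
        ts = simulate_population(SimConfig(n_cells=1000, seed=13))
        kept, _ = apply_qc(ts)
        snap = kept.endpoint_values("PPARG")
        thr = histogram_midpoint_threshold(snap)
        assert percent_differentiated(snap.values, thr) == pytest.approx(0.60, abs=0.04)


class TestHitTimes:
    def test_canonical_crossing(self, canonical):
        ts = TrajectorySet(TimeGrid(), [canonical])
        ht = threshold_hit_times(ts, 100 * (1 + 7 * 0.253), {"canonical": "differentiated"})
        assert ht.mean == pytest.approx(32.1, abs=0.02)

    def test_never_crossing_counted(self):
        g = TimeGrid(0, 0.2, 11)
        tr = CellTrace("low", "c", g.times(), {"PPARG": np.full(11, 1.0)})
        hi = CellTrace("hi", "c", g.times(), {"PPARG": np.linspace(1, 10, 11)})
        ht = threshold_hit_times(TrajectorySet(g, [tr, hi]), 5.0,
                                 {"low": "differentiated", "hi": "differentiated"})
        assert ht.n_never == 1 and "hi" in ht.hit_times

    def test_starting_above_threshold_hits_first_frame(self):
        g = TimeGrid(0, 0.2, 5)
        tr = CellTrace("x", "c", g.times(), {"PPARG": np.full(5, 9.0)})
        ht = threshold_hit_times(TrajectorySet(g, [tr]), 5.0, {"x": "differentiated"})
        assert ht.hit_times["x"] == 0.0

    def test_interpolation_between_frames(self):
        g = TimeGrid(0, 1.0, 3)
        tr = CellTrace("x", "c", g.times(), {"PPARG": np.array([0.0, 10.0, 20.0])})
        ht = threshold_hit_times(TrajectorySet(g, [tr]), 2.5, {"x": "differentiated"})
        assert ht.hit_times["x"] == pytest.approx(0.25)

    def test_no_differentiated_cells_errors(self, canonical):
        ts = TrajectorySet(TimeGrid(), [canonical])
        with pytest.raises(ValueError):
            threshold_hit_times(ts, 200.0, {"canonical": "undifferentiated"})
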