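"""FLIPR metrics, swelling AUC, Ussing currents, blot folds and tests."""

import numpy as np
import pandas as pd
import pytest

from cftrscreen import (
    AssayTrace,
    UssingRecording,
    fis_auc,
    flipr_fsk_response,
    flipr_inhibitor_response,
    normalize_and_test,
    ussing_metrics,
    wb_fold_change,
)
from cftrscreen.assays import pooled_t_test


def _trace(values, events, dt=10.0):
    values = np.asarray(values, dtype=float)
    return AssayTrace(times=np.arange(len(values)) * dt, values=values, events=events)


class TestFliprMetrics:
    def test_flat_trace_gives_unity(self):
        trace = _trace([100] * 12, [("fsk", 45.0), ("inhibitor", 85.0)])
        assert flipr_fsk_response(trace) == 1.0
        assert flipr_inhibitor_response(trace) == 1.0

    def test_constructed_peak(self):
        trace = _trace([100, 100, 100, 100, 100, 120, 150, 140],
                       [("fsk", 45.0)])
        assert flipr_fsk_response(trace) == pytest.approx(1.5)

    def test_hand_built_twelve_point_trace(self):
        """Baseline 100 (5 scans), rise to 150, inhibitor decay to 100:
        Maximum F/F0 = 1.5, F1/F-inh = 140/100 (last pre-inhibitor scan
        over the post-inhibitor minimum)."""
        values = [100, 100, 100, 100, 100, 130, 150, 140, 120, 110, 100, 105]
        trace = _trace(values, [("fsk", 45.0), ("inhibitor", 75.0)])
        assert flipr_fsk_response(trace) == pytest.approx(1.5)
        assert flipr_inhibitor_response(trace) == pytest.approx(140.0 / 100.0)

    def test_peak_search_stops_at_inhibitor(self):
        # post-inhibitor overshoot must not count toward Maximum F/F0
        values = [100, 100, 100, 100, 100, 120, 130, 900]
        trace = _trace(values, [("fsk", 45.0), ("inhibitor", 65.0)])
        assert flipr_fsk_response(trace) == pytest.approx(1.3)

    def test_scale_invariance(self):
        values = np.array([100, 100, 100, 100, 100, 130, 150, 140, 120, 100])
        events = [("fsk", 45.0), ("inhibitor", 75.0)]
        a, b = _trace(values, events), _trace(values * 7.3, events)
        assert flipr_fsk_response(a) == pytest.approx(flipr_fsk_response(b))
        assert flipr_inhibitor_response(a) == pytest.approx(
            flipr_inhibitor_response(b)
        )

    def test_baseline_mode_last_scan(self):
        values = [80, 100, 100, 100, 120, 150]
        trace = _trace(values, [("fsk", 35.0)])
        assert flipr_fsk_response(trace, baseline="last") == pytest.approx(1.5)
        assert flipr_fsk_response(trace) == pytest.approx(150.0 / 95.0)

    def test_nonpositive_baseline_rejected(self):
        trace = _trace([0, 0, 0, 0, 0, 10], [("fsk", 45.0)])
        with pytest.raises(ValueError, match="F0 <= 0"):
            flipr_fsk_response(trace)

    def test_missing_event_rejected(self):
        trace = _trace([100, 100, 120], [("fsk", 5.0)])
        with pytest.raises(ValueError, match="no 'inhibitor' event|no scans"):
            flipr_inhibitor_response(trace)

    def test_noisy_traces_recover_amplitude_on_average(self):
        """Mean estimate over 50 seeded noisy traces lands within Monte-Carlo
        error of the configured 1.5 peak ratio."""
        from cftrscreen import TraceSimConfig, simulate_trace

        vals = [
            flipr_fsk_response(
                simulate_trace(
                    TraceSimConfig(response_amplitude=0.5, noise_sd=1.0, seed=s)
                )
            )
            for s in range(50)
        ]
        vals = np.array(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        # max over noisy scans biases slightly upward; allow 3 SE + bias room
        assert abs(vals.mean() - 1.5) < 3 * se + 0.02


class TestNormalizeAndTest:
    def test_identical_condition_fold_one_t_zero(self):
        df = pd.DataFrame({
            "condition": ["ctrl"] * 3 + ["same"] * 3,
            "value": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
        })
        out = normalize_and_test(df, "ctrl").set_index("condition")
        assert out.loc["same", "fold_vs_control"] == pytest.approx(1.0)
        assert out.loc["same", "t"] == pytest.approx(0.0)
        assert out.loc["same", "p_value"] == pytest.approx(1.0)

    def test_matches_textbook_pooled_variance_formula(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])
        t, p = pooled_t_test(a, b)
        # hand computation: sp^2 = 1, t = -3 / sqrt(2/3), df = 4
        t_hand = -3.0 / np.sqrt(2.0 / 3.0)
        assert t == pytest.approx(t_hand)
        from scipy import stats

        assert p == pytest.approx(2 * stats.t.sf(abs(t_hand), df=4))

    def test_missing_control_rejected(self):
        df = pd.DataFrame({"condition": ["x"] * 3, "value": [1, 2, 3]})
        with pytest.raises(ValueError, match="control group"):
            normalize_and_test(df, "ctrl")

    def test_stars_assigned_by_pvalue(self):
        df = pd.DataFrame({
            "condition": ["ctrl"] * 3 + ["big"] * 3,
            "value": [1.0, 1.1, 0.9, 50.0, 51.0, 49.0],
        })
        out = normalize_and_test(df, "ctrl").set_index("condition")
        assert out.loc["big", "stars"] == "***"


class TestFisAUC:
    def test_constant_baseline_gives_zero(self):
        trace = AssayTrace(times=np.linspace(0, 60, 7), values=np.full(7, 100.0),
                           events=[("fsk", 0.0)])
        assert fis_auc(trace) == 0.0

    def test_linear_rise_triangle_area(self):
        trace = AssayTrace(
            times=np.linspace(0, 60, 13),
            values=np.linspace(100, 160, 13),
            events=[("fsk", 0.0)],
        )
        assert fis_auc(trace) == pytest.approx(1800.0)

    def test_piecewise_series_matches_fine_quadrature(self, rng):
        times = np.linspace(0, 90, 10)
        values = 100 + rng.normal(20, 10, size=10).cumsum() / 5
        trace = AssayTrace(times=times, values=values, events=[("fsk", 0.0)])
        # oracle: trapezoid on a dense interpolated grid, cut at t = 60
        tt = np.linspace(0, 60, 60_001)
        vv = np.interp(tt, times, values)
        oracle = np.trapezoid(vv - 100.0, tt)
        assert fis_auc(trace) == pytest.approx(oracle, rel=1e-6)

    def test_additivity_over_subintervals(self):
        times = np.linspace(0, 60, 13)
        v1 = np.linspace(100, 140, 13)
        v2 = 100 + np.sin(times / 10) * 20
        tr = lambda v: AssayTrace(times=times, values=v, events=[("fsk", 0.0)])
        # linear in (value - 100): AUC(v1 + v2 - 100) = AUC(v1) + AUC(v2)
        assert fis_auc(tr(v1 + v2 - 100)) == pytest.approx(
            fis_auc(tr(v1)) + fis_auc(tr(v2))
        )

    def test_short_series_integrates_to_last_point_with_warning(self):
        trace = AssayTrace(times=np.linspace(0, 30, 7),
                           values=np.linspace(100, 130, 7),
                           events=[("fsk", 0.0)])
        with pytest.warns(UserWarning, match="ends at"):
            auc = fis_auc(trace)
        assert auc == pytest.approx(0.5 * 30 * 30)

    def test_shrinkage_contributes_negatively(self):
        trace = AssayTrace(times=np.linspace(0, 60, 13),
                           values=np.linspace(100, 40, 13),
                           events=[("fsk", 0.0)])
        assert fis_auc(trace) == pytest.approx(-1800.0)


class TestUssing:
    def test_ieq_is_pointwise_ohms_law(self, rng):
        t = np.arange(30.0)
        vte = rng.normal(10, 2, size=30)
        rte = rng.uniform(500, 1500, size=30)
        rec = UssingRecording(times=t, vte=vte, rte=rte, events=[("fsk", 15.0)])
        m = ussing_metrics(rec)
        assert np.allclose(m.ieq, 1000.0 * vte / rte)

    def test_constant_recording_units(self):
        t = np.arange(10.0)
        rec = UssingRecording(times=t, vte=np.full(10, 10.0),
                              rte=np.full(10, 1000.0), events=[("fsk", 4.5)])
        m = ussing_metrics(rec)
        assert np.allclose(m.ieq, 10.0)  # 10 mV / 1000 Ohm.cm2 = 10 uA/cm2
        assert m.delta_ieq_fsk == pytest.approx(0.0)

    def test_step_response_delta(self):
        t = np.arange(20.0)
        vte = np.where(t < 10, 5.0, 15.0)
        rec = UssingRecording(times=t, vte=vte, rte=np.full(20, 1000.0),
                              events=[("fsk", 9.5)])
        assert ussing_metrics(rec).delta_ieq_fsk == pytest.approx(10.0)

    def test_baseline_window_starts_after_amiloride(self):
        t = np.arange(30.0)
        vte = np.concatenate([np.full(10, 20.0), np.full(10, 5.0), np.full(10, 15.0)])
        rec = UssingRecording(
            times=t, vte=vte, rte=np.full(30, 1000.0),
            events=[("amiloride", 9.5), ("fsk", 19.5)],
        )
        # baseline must use the post-amiloride 5 mV segment, not the 20 mV one
        assert ussing_metrics(rec).delta_ieq_fsk == pytest.approx(10.0)

    def test_inhibitor_delta(self):
        t = np.arange(30.0)
        vte = np.concatenate([np.full(10, 5.0), np.full(10, 15.0), np.full(10, 7.0)])
        rec = UssingRecording(
            times=t, vte=vte, rte=np.full(30, 1000.0),
            events=[("fsk", 9.5), ("inhibitor", 19.5)],
        )
        m = ussing_metrics(rec)
        assert m.delta_ieq_fsk == pytest.approx(10.0)
        assert m.delta_ieq_inhibitor == pytest.approx(-8.0)

    def test_noisy_step_recovered_within_three_se(self, rng):
        """Median-based delta over 100 seeded noisy recordings recovers the
        configured 10 uA/cm2 step within 3 SE."""
        deltas = []
        t = np.arange(40.0)
        for _ in range(100):
            vte = np.where(t < 20, 5.0, 15.0) + rng.normal(0, 1.0, size=40)
            rec = UssingRecording(times=t, vte=vte, rte=np.full(40, 1000.0),
                                  events=[("fsk", 19.5)])
            deltas.append(ussing_metrics(rec).delta_ieq_fsk)
        deltas = np.array(deltas)
        se = deltas.std(ddof=1) / 10.0
        assert abs(deltas.mean() - 10.0) < 3 * se

    def test_missing_fsk_event_rejected(self):
        rec = UssingRecording(times=np.arange(5.0), vte=np.ones(5),
                              rte=np.ones(5) * 100, events=[])
        with pytest.raises(ValueError, match="no 'fsk' event"):
            ussing_metrics(rec)

    def test_nonpositive_resistance_rejected(self):
        with pytest.raises(ValueError, match="Rte must be positive"):
            UssingRecording(times=np.arange(3.0), vte=np.ones(3),
                            rte=np.array([100.0, 0.0, 100.0]), events=[])


class TestWesternBlot:
    def _quants(self):
        return pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(6)],
            "condition": ["base"] * 3 + ["kd"] * 3,
            "band_b": [1.0, 1.2, 0.8, 2.0, 2.4, 1.6],
            "band_c": [0.5, 0.5, 0.5, 2.0, 2.0, 2.0],
            "calnexin": [1.0, 1.0, 1.0, 1.0, 1.0, 1.0],
        })

    def test_baseline_samples_average_to_fold_one(self):
        folds, _ = wb_fold_change(self._quants(), "base")
        base = folds[folds["condition"] == "base"]
        assert base["band_b_fold"].mean() == pytest.approx(1.0)
        assert base["band_c_fold"].mean() == pytest.approx(1.0)

    def test_fold_arithmetic_with_calnexin_normalization(self):
        quants = pd.DataFrame({
            "sample_id": ["a", "b", "c"],
            "condition": ["base", "base", "kd"],
            "band_b": [1.0, 1.0, 2.0],
            "band_c": [1.0, 1.0, 2.0],
            "calnexin": [1.0, 1.0, 0.5],
        })
        folds, _ = wb_fold_change(quants, "base")
        kd = folds[folds["condition"] == "kd"].iloc[0]
        assert kd["band_b_fold"] == pytest.approx(4.0)

    def test_anova_matches_sum_of_squares_closed_form(self, rng):
        conds = np.repeat(["a", "b", "c"], 3)
        vals = rng.normal(5, 1, size=9)
        quants = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(9)],
            "condition": conds,
            "band_b": vals,
            "band_c": vals * 2,
            "calnexin": np.ones(9),
        })
        _, tests = wb_fold_change(quants, "a")
        grand = vals.mean()
        groups = [vals[conds == c] for c in "abc"]
        ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
        f_hand = (ss_between / 2) / (ss_within / 6)
        assert tests.loc[tests["band"] == "band_b", "anova_F"].iloc[0] == pytest.approx(
            f_hand
        )

    def test_zero_calnexin_sample_excluded_with_warning(self):
        quants = self._quants()
        quants.loc[5, "calnexin"] = 0.0
        with pytest.warns(UserWarning, match="non-positive calnexin"):
            folds, _ = wb_fold_change(quants, "base")
        assert len(folds) == 5

    def test_missing_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            wb_fold_change(self._quants(), "nope")
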