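import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from chipcal.simulate import SimConfig, make_traces
from chipcal.soce import (
    FluorescenceTrace, cohort_summary, metrics_frame, normalize_trace,
    segment_phases, wave_metrics,
)


def _trace(raw, background=0.0, tg=100.0, ca=400.0, dt=6.0, **kw):
    raw = np.asarray(raw, dtype=float)
    times = np.arange(len(raw)) * dt
    return FluorescenceTrace(times, raw, background, tg, ca, **kw)


class TestNormalizeTrace:
    def test_constant_trace(self):
        tr = _trace(np.full(101, 10.0), background=2.0)
        assert np.allclose(normalize_trace(tr), 1.0)

    def test_worked_example(self):
        tr = _trace([12.0, 20.0, 12.0], background=2.0, tg=6.0, ca=12.0)
        assert np.allclose(normalize_trace(tr), [1.0, 1.8, 1.0])

    def test_background_exceeding_signal_rejected(self):
        tr = _trace([12.0, 20.0, 12.0], background=12.0, tg=6.0, ca=12.0)
        with pytest.raises(ValueError, match="background"):
            normalize_trace(tr)

    @given(
        st.lists(st.floats(1, 1000), min_size=3, max_size=80),
        st.floats(0, 0.99),
    )
    def test_minimum_exactly_one(self, raw, bg_frac):
        raw = np.asarray(raw)
        bg = float(raw.min() * bg_frac)
        tr = _trace(raw, background=bg, tg=1.0, ca=2.0, dt=6.0)
        assert normalize_trace(tr).min() == 1.0


class TestSegmentPhases:
    def test_protocol_windows(self):
        tr = _trace(np.full(101, 5.0))  # 0..600 s at 6 s
        w = segment_phases(tr)
        assert w.pre == (0.0, 100.0)
        assert w.wave1 == (100.0, 400.0)
        assert w.wave2 == (400.0, 600.0)

    def test_tg_at_start_warns(self):
        tr = _trace(np.full(101, 5.0), tg=0.0, ca=400.0)
        with pytest.warns(UserWarning, match="pre-window"):
            segment_phases(tr)

    def test_event_outside_record_rejected(self):
        tr = _trace(np.full(101, 5.0), tg=100.0, ca=700.0)
        with pytest.raises(ValueError, match="within"):
            segment_phases(tr)

    def test_ca_before_tg_rejected(self):
        with pytest.raises(ValueError, match="precede"):
            _trace(np.full(101, 5.0), tg=400.0, ca=100.0)


class TestWaveMetrics:
    def test_flat_trace_all_zero(self):
        tr = _trace(np.full(101, 10.0), background=9.0)
        m = wave_metrics(tr)
        assert m.baseline_level == 1.0
        for f in ("wave1_peak", "wave2_peak", "wave1_auc",
                  "wave2_auc_total", "wave2_auc_early", "wave2_auc_late"):
            assert getattr(m, f) == 0.0

    def test_rectangular_pulse_area_split(self):
        """Unit-height 60 s rectangle filling the SOCE window: total area 60
        splits 50/10 at the 50 s early-phase boundary."""
        times = np.arange(0.0, 601.0, 6.0)
        raw = np.ones_like(times)
        raw[times >= 540.0] = 2.0
        tr = FluorescenceTrace(times, raw, 0.0, 100.0, 540.0)
        m = wave_metrics(tr)
        assert m.wave2_peak == pytest.approx(1.0)
        assert m.wave2_auc_total == pytest.approx(60.0)
        assert m.wave2_auc_early == pytest.approx(50.0)
        assert m.wave2_auc_late == pytest.approx(10.0)

    def test_auc_additivity(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            raw = 10.0 + rng.uniform(0, 5, size=101)
            tr = _trace(raw, background=1.0)
            m = wave_metrics(tr, early_s=float(rng.uniform(10, 150)))
            assert m.wave2_auc_early + m.wave2_auc_late == pytest.approx(
                m.wave2_auc_total, abs=1e-9
            )

    def test_shift_invariance_with_matched_background(self):
        rng = np.random.default_rng(5)
        raw = 50.0 + rng.uniform(0, 20, size=101)
        a = wave_metrics(_trace(raw, background=10.0))
        b = wave_metrics(_trace(raw + 7.0, background=17.0))
        for f in ("wave1_peak", "wave2_peak", "wave2_auc_total"):
            assert getattr(a, f) == pytest.approx(getattr(b, f))

    def test_floor_baseline_mode(self):
        tr = _trace(np.full(101, 10.0), background=5.0)
        m = wave_metrics(tr, baseline="floor")
        assert m.baseline_level == 1.0


class TestMakeTraces:
    def test_grid_has_101_samples(self):
        traces, _ = make_traces(SimConfig(seed=0))
        assert all(len(t.times) == 101 for t in traces)
        assert traces[0].times[-1] == 600.0

    def test_determinism(self):
        a, _ = make_traces(SimConfig(seed=3))
        b, _ = make_traces(SimConfig(seed=3))
        assert all(np.array_equal(x.raw, y.raw) for x, y in zip(a, b))

    def test_zero_soce_zero_noise_has_no_second_wave(self):
        cfg = SimConfig(seed=0)
        cfg.traces.noise_sd = 0.0
        cfg.traces.cell_scatter_sd = 0.0
        cfg.traces.soce_scale = {"flat": 0.0}
        cfg.traces.n_cells = 3
        traces, _ = make_traces(cfg)
        for tr in traces:
            m = wave_metrics(tr)
            # only the decayed tail of the first wave can leak in
            assert m.wave2_peak <= 0.005
            assert m.wave1_peak > 0.5

    def test_ca_before_tg_rejected(self):
        cfg = SimConfig(seed=0)
        cfg.traces.ca_time_s = 50.0
        with pytest.raises(ValueError):
            make_traces(cfg)

    def test_amplitude_ratio_recovery(self):
        """Cohorts planted at SOCE scale 1.0 vs 1.4 recover the ratio."""
        cfg = SimConfig(seed=0)
        cfg.traces.soce_scale = {"lo": 1.0, "hi": 1.4}
        traces, _ = make_traces(cfg)
        df = metrics_frame([wave_metrics(t) for t in traces])
        med = df.groupby("condition")["wave2_peak"].median()
        assert med["hi"] / med["lo"] == pytest.approx(1.4, rel=0.10)


class TestCohortSummary:
    def _df(self, values_by_cond):
        rows = []
        for cond, vals in values_by_cond.items():
            for i, v in enumerate(vals):
                rows.append({
                    "cell_id": f"{cond}{i}", "condition": cond, "baseline_level": 1.0,
                    "wave1_peak": v, "wave2_peak": v, "wave1_auc": v,
                    "wave2_auc_total": v, "wave2_auc_early": v, "wave2_auc_late": v,
                })
        return pd.DataFrame(rows)

    def test_single_cell_median_is_value(self):
        summary, _ = cohort_summary(self._df({"a": [2.5], "b": [1.0]}))
        row = summary.query("condition == 'a' and metric == 'wave2_peak'")
        assert row["median"].iloc[0] == 2.5

    def test_identical_conditions_unit_ratios(self):
        _, ratios = cohort_summary(self._df({"a": [1.0, 2.0], "b": [1.0, 2.0]}))
        assert np.allclose(ratios["median_ratio"], 1.0)

    def test_permutation_invariance(self):
        df = self._df({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        s1, r1 = cohort_summary(df)
        s2, r2 = cohort_summary(df.sample(frac=1.0, random_state=0))
        pd.testing.assert_frame_equal(s1, s2)
        pd.testing.assert_frame_equal(r1, r2)
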