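"""Pacing and clamp protocols: capture, convergence, carry-over, and the
self-clamp fixed point."""

import numpy as np
import pytest

from cardiopop import build_model, ParameterScaling
from cardiopop.biomarkers import beat_biomarkers, check_capture
from cardiopop.engine import StepSchedule
from cardiopop.protocols import (DEFAULT_CLS, PacingProtocol, ap_clamp, pace,
                                 run_restitution)


class TestPacingBasics:
    def test_baseline_cl600_no_alternans(self, baseline_restitution_series):
        series = baseline_restitution_series[600.0]
        apds = [beat_biomarkers(b).APD for b in series]
        assert all(check_capture(b) for b in series)
        assert max(apds) - min(apds) < 1.0

    def test_zero_record_returns_state_only(self, baseline_spec,
                                            baseline_state):
        series = pace(baseline_spec, 600.0, 2, 0, initial_state=baseline_state)
        assert len(series) == 0
        assert series.final_state is not None
        assert series.final_state.shape == np.asarray(baseline_state).shape

    def test_cl_validation(self, baseline_spec):
        with pytest.raises(ValueError):
            pace(baseline_spec, 150.0, 1, 1)
        with pytest.raises(ValueError):
            pace(baseline_spec, 600.0, -1, 1)

    def test_protocol_validation(self):
        with pytest.raises(ValueError):
            PacingProtocol(n_record=3)
        with pytest.raises(ValueError):
            PacingProtocol(n_record=2)
        with pytest.raises(ValueError):
            PacingProtocol(cl_list=(600.0, 150.0))
        assert PacingProtocol().extended().cl_list[-1] == 200.0

    def test_prebeat_convergence(self, baseline_spec, baseline_state):
        """Doubling pre-beats at the converged scale changes APD < 1 ms.

        Absolute APD adapts slowly (intracellular Na accumulation has a
        several-hundred-beat time constant), so the doubling invariant is
        asserted at 800 pre-beats; shorter counts must show a shrinking
        doubling gap (monotone approach to the attractor).
        """
        apd = {}
        for pb in (100, 200, 800, 1600):
            s = pace(baseline_spec, 500.0, pb, 1,
                     initial_state=baseline_state)
            apd[pb] = beat_biomarkers(s[0]).APD
        assert abs(apd[800] - apd[1600]) < 1.0
        assert abs(apd[800] - apd[1600]) < abs(apd[100] - apd[200])

    def test_step_refinement_convergence(self, baseline_spec, baseline_state):
        """Halving every integrator step changes APD90 by < 0.5 ms."""
        from cardiopop.engine import RECORD_SCHEDULE

        fine = RECORD_SCHEDULE.halved()
        a = pace(baseline_spec, 1000.0, 3, 1, initial_state=baseline_state)
        b = pace(baseline_spec, 1000.0, 3, 1, initial_state=baseline_state,
                 schedule=fine, prebeat_schedule=fine)
        assert abs(beat_biomarkers(a[0]).APD
                   - beat_biomarkers(b[0]).APD) < 0.5

    def test_schedule_must_divide_sampling(self):
        with pytest.raises(ValueError):
            StepSchedule(dt_mid=0.03)


class TestCaptureFailure:
    def test_sodiumless_model_not_captured(self, baseline_state):
        spec = build_model(ParameterScaling(s_GNa=0.0))
        series = pace(spec, 600.0, 0, 1, initial_state=baseline_state)
        assert not check_capture(series[0])


class TestRestitution:
    def test_baseline_is_normal_across_ladder(self, baseline_spec,
                                              baseline_state):
        proto = PacingProtocol(cl_list=DEFAULT_CLS, n_prebeats=100, n_record=4)
        res = run_restitution(baseline_spec, proto,
                              initial_state=baseline_state)
        assert res.captured.all()
        assert np.all(res.dapd < 5.0)
        # APD shortens monotonically with CL (restitution)
        assert np.all(np.diff(res.apd_mean) < 0)
        # DI = CL - APD of preceding beat
        assert np.allclose(res.mean_di, res.cls - res.apd_mean, atol=1.0)

    def test_early_rejection_records_first_violated_cl(self, baseline_spec,
                                                       baseline_state):
        proto = PacingProtocol(cl_list=DEFAULT_CLS, n_prebeats=5, n_record=4)
        ranges = {cl: (0.0, 1.0) for cl in DEFAULT_CLS}  # impossible envelope
        res = run_restitution(baseline_spec, proto,
                              initial_state=baseline_state, apd_ranges=ranges)
        assert res.rejected_at == 600.0
        assert not res.captured[1:].any()  # remaining CLs skipped


class TestAPClamp:
    def test_self_clamp_fixed_point(self, baseline_restitution_series):
        """Clamping with the model's own steady AP reproduces its free CaT."""
        series = baseline_restitution_series[600.0]
        free_amp = beat_biomarkers(series[0]).CaTamp
        vcmd = series[0].v.copy()
        spec = build_model()
        clamped = ap_clamp(spec, vcmd, 3,
                           initial_state=series.final_state)
        amps = [beat_biomarkers_cat(b) for b in clamped]
        assert amps[-1] == pytest.approx(free_amp, rel=0.02)

    def test_clamp_sampling_validation(self, baseline_spec):
        with pytest.raises(ValueError):
            ap_clamp(baseline_spec, np.linspace(-87, 30, 100), 1,
                     sample_dt=2.0)

    @pytest.mark.parametrize("which", ["long", "short"])
    def test_calcium_alternans_persist_under_identical_beat_clamp(self, which):
        """Clamping an alternans model with two identical beats (L+L or
        S+S) removes APD alternans by construction, yet the calcium
        transient keeps alternating: Ca alternans are primary, not a
        consequence of APD alternans."""
        from cardiopop import initial_state
        from cardiopop.presets import alternans_presets

        spec = build_model(alternans_presets()["eye_large"])
        state = initial_state()
        for cl in (600.0, 550.0):
            state = pace(spec, cl, 150, 0, initial_state=state).final_state
        series = pace(spec, 500.0, 150, 4, initial_state=state)
        apds = [beat_biomarkers(b).APD for b in series]
        assert np.mean(np.abs(np.diff(apds))) > 5.0  # alternans established
        idx = int(np.argmax(apds[:2])) if which == "long" \
            else int(np.argmin(apds[:2]))
        vcmd = np.concatenate([series[idx].v, series[idx].v])
        clamped = ap_clamp(spec, vcmd, 6, initial_state=series.final_state)
        last = clamped[-1]
        n = len(last) // 2
        amp1 = float(np.ptp(last.cai[:n]))
        amp2 = float(np.ptp(last.cai[n:]))
        mean_amp = 0.5 * (amp1 + amp2)
        assert abs(amp1 - amp2) > 0.05 * mean_amp  # CaT alternans persist

    def test_clamp_beat_to_beat_stability(self, baseline_restitution_series):
        series = baseline_restitution_series[600.0]
        spec = build_model()
        clamped = ap_clamp(spec, series[0].v.copy(), 4,
                           initial_state=series.final_state)
        amps = [beat_biomarkers_cat(b) for b in clamped]
        assert abs(amps[-1] - amps[-2]) < 0.02 * amps[-1]


def beat_biomarkers_cat(beat):
    from cardiopop.biomarkers import cat_biomarkers
    return cat_biomarkers(beat).CaTamp
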