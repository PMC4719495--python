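"""Cell-model construction, scaling semantics, conservation and
directional sensitivities of the epicardial ORd transcription."""

import numpy as np
import pytest

from cardiopop import (KineticsScaling, ParameterScaling, build_model,
                       derivatives, initial_state)
from cardiopop.biomarkers import beat_biomarkers, check_capture
from cardiopop.engine import REC, Stimulus, run_paced
from cardiopop.ord import (N_STATE, STATE_NAMES, evaluate_currents,
                           total_calcium)
from cardiopop.protocols import pace
from cardiopop.trace import split_record


class TestParameterScaling:
    def test_identity_is_default(self):
        spec = build_model()
        assert np.allclose(spec.p, 1.0)

    def test_factor_range_enforced(self):
        with pytest.raises(ValueError):
            ParameterScaling(s_GKr=2.1)
        with pytest.raises(ValueError):
            ParameterScaling(s_GNa=-0.1)
        ParameterScaling(s_GNa=0.0)  # zero allowed: current removed

    def test_kinetics_range_enforced(self):
        with pytest.raises(ValueError):
            KineticsScaling(m_tau_f=1.6)
        with pytest.raises(ValueError):
            KineticsScaling(m_tau_d=0.4)

    def test_array_round_trip(self):
        s = ParameterScaling(s_GCaL=1.5, s_PJup=0.3)
        assert ParameterScaling.from_array(s.as_array()) == s


class TestRestingBehaviour:
    def test_resting_equilibrium(self, baseline_spec, baseline_state):
        """After a long unpaced interval, dVm/dt is numerically zero."""
        _, _, y = run_paced(baseline_spec, baseline_state, 5000.0, 4, 0,
                            stimulus=Stimulus(amplitude=0.0))
        dy = derivatives(0.0, y, baseline_spec, i_stim=0.0)
        assert abs(dy[0]) < 1e-3

    def test_constant_state_gives_constant_observables(self, baseline_spec,
                                                       baseline_state):
        """Quiescent quasi-steady state: observables essentially flat.

        Slow SR re-equilibration persists for minutes of model time, so the
        tolerance is per-500 ms drift, not machine precision.
        """
        _, _, y = run_paced(baseline_spec, baseline_state, 5000.0, 20, 0,
                            stimulus=Stimulus(amplitude=0.0))
        rec, _, _ = run_paced(baseline_spec, y, 500.0, 0, 1,
                              stimulus=Stimulus(amplitude=0.0))
        for ch in ("v", "cai", "cajsr", "ICaL", "INaCa_i"):
            col = rec[:, REC[ch]]
            assert np.ptp(col) <= max(1e-6, 3e-3 * abs(np.mean(col)) + 1e-9)


class TestScalingSemantics:
    def test_zero_sodium_conductance_removes_upstroke(self, baseline_state):
        spec = build_model(ParameterScaling(s_GNa=0.0))
        series = pace(spec, 600.0, 0, 1, initial_state=baseline_state)
        assert not check_capture(series[0])
        assert np.max(series[0].v) < 0.0

    def test_rmp_most_sensitive_to_gk1(self, baseline_spec, baseline_state):
        """RMP is mainly determined by the inward-rectifier conductance:
        halving G_K1 shifts diastolic Vm measurably, and more than halving
        any of the other repolarizing conductances does."""
        rmp_base = beat_biomarkers(
            pace(baseline_spec, 1000.0, 50, 1,
                 initial_state=baseline_state)[0]).RMP
        shifts = {}
        for name in ("s_GK1", "s_GKr", "s_GKs", "s_Gto"):
            spec = build_model(ParameterScaling(**{name: 0.5}))
            rmp = beat_biomarkers(
                pace(spec, 1000.0, 50, 1,
                     initial_state=baseline_state)[0]).RMP
            shifts[name] = abs(rmp - rmp_base)
        assert shifts["s_GK1"] > 0.1
        assert shifts["s_GK1"] == max(shifts.values())

    def test_zero_scaling_removes_current_exactly(self, baseline_state):
        spec = build_model(ParameterScaling(s_GNaCa=0.0))
        cur = evaluate_currents(baseline_state, spec)
        assert cur["INaCa_i"] == 0.0 and cur["INaCa_ss"] == 0.0

    def test_kinetics_identity_bitwise(self, baseline_spec, baseline_state):
        spec = build_model(kinetics=KineticsScaling(1.0, 1.0, 1.0))
        d0 = derivatives(0.0, baseline_state, baseline_spec)
        d1 = derivatives(0.0, baseline_state, spec)
        assert np.array_equal(d0, d1)


class TestConservation:
    def test_calcium_conservation_over_one_beat(self, baseline_spec,
                                                baseline_state):
        """Total cell Ca changes only by the net sarcolemmal Ca flux."""
        from cardiopop.balance import scb_per_beat

        rec, integ, y1 = run_paced(baseline_spec, baseline_state, 1000.0, 0, 1)
        beat = split_record(rec, 1000.0, integ=integ)[0]
        d_total = total_calcium(y1) - total_calcium(baseline_state)  # mM cyt
        flux = scb_per_beat(beat) * 1e-3                             # mM cyt
        assert abs(d_total - flux) < 1e-3 * total_calcium(baseline_state)

    def test_charge_bookkeeping(self, baseline_spec, baseline_state):
        """dVm/dt equals minus the sum of all membrane currents."""
        dy = derivatives(0.0, baseline_state, baseline_spec, i_stim=-80.0)
        cur = evaluate_currents(baseline_state, baseline_spec, i_stim=-80.0)
        total = sum(cur[k] for k in
                    ("INa", "INaL", "Ito", "ICaL", "ICaNa", "ICaK", "IKr",
                     "IKs", "IK1", "INaCa_i", "INaCa_ss", "INaK", "IKb",
                     "INab", "ICab", "IpCa"))
        assert dy[0] == pytest.approx(-(total - 80.0), rel=1e-12)


class TestIntegratorCrossCheck:
    def test_rush_larsen_matches_lsoda(self, baseline_spec, baseline_state):
        """APD90 from the production integrator agrees with an adaptive
        stiff solve of the same right-hand side within 1 ms."""
        from scipy.integrate import solve_ivp

        rec, _, _ = run_paced(baseline_spec, baseline_state, 1000.0, 0, 1)
        beat_rl = split_record(rec, 1000.0)[0]
        apd_rl = beat_biomarkers(beat_rl).APD

        y = np.array(baseline_state, dtype=float)
        sol1 = solve_ivp(derivatives, (0.0, 0.5), y, method="LSODA",
                         args=(baseline_spec, -80.0), rtol=1e-8, atol=1e-10,
                         max_step=0.05)
        sol2 = solve_ivp(derivatives, (0.5, 1000.0), sol1.y[:, -1],
                         method="LSODA", args=(baseline_spec, 0.0),
                         rtol=1e-8, atol=1e-10, max_step=1.0,
                         t_eval=np.arange(0.5, 1000.0, 0.5))
        from conftest import synthetic_trace
        # prepend the pre-stimulus sample so RMP/APA are referenced to rest
        t = np.concatenate([[0.0], sol2.t])
        v = np.concatenate([[y[0]], sol2.y[0]])
        cai = np.concatenate([[y[STATE_NAMES.index("cai")]],
                              sol2.y[STATE_NAMES.index("cai")]])
        beat_ls = synthetic_trace(t, v=v, cai=cai)
        apd_ls = beat_biomarkers(beat_ls).APD
        assert apd_rl == pytest.approx(apd_ls, abs=1.0)

    def test_nonfinite_state_reported(self, baseline_spec):
        bad = np.array(initial_state(), dtype=float)
        bad[STATE_NAMES.index("cass")] = -1e-9  # unphysical
        with pytest.raises(FloatingPointError):
            bad[STATE_NAMES.index("nai")] = -7.0
            derivatives(0.0, bad, baseline_spec)


class TestObservables:
    def test_jrel_pulse_follows_upstroke(self, baseline_beat_cl1000):
        beat = baseline_beat_cl1000[0]
        dvdt = np.gradient(beat.v, beat.t)
        t_up = beat.t[np.argmax(dvdt)]
        jrel = beat.Jrel
        t_rel = beat.t[np.argmax(jrel > 0.1 * np.max(jrel))]
        assert 0.0 <= t_rel - t_up <= 10.0

    def test_trace_export_schema(self, baseline_beat_cl1000, tmp_path):
        beat = baseline_beat_cl1000[0]
        df = beat.to_dataframe()
        assert {"t_ms", "Vm_mV", "Cai_mM", "CaJSR_mM", "Jrel_mM_per_ms",
                "Jup_mM_per_ms", "ICaL_A_per_F"} <= set(df.columns)
        beat.to_csv(tmp_path / "beat.csv")
        import pandas as pd
        back = pd.read_csv(tmp_path / "beat.csv")
        assert np.allclose(back["Vm_mV"], beat.v)

    def test_hdf5_export(self, baseline_beat_cl1000, tmp_path):
        import h5py
        with h5py.File(tmp_path / "beat.h5", "w") as fh:
            baseline_beat_cl1000[0].to_hdf5(fh.create_group("beat0"))
        with h5py.File(tmp_path / "beat.h5") as fh:
            assert "beat0/Vm_mV" in fh
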