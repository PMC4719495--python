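"""Biomarker extraction on synthetic waveforms with closed-form answers,
plus invariance properties."""

import numpy as np
import pytest

from cardiopop.biomarkers import (alternans_magnitude, ap_biomarkers,
                                  beat_biomarkers, cat_biomarkers,
                                  check_capture)
from cardiopop.trace import BeatSeries

from conftest import synthetic_trace


def trapezoid_ap(dt=0.5, rest=-85.0, peak=40.0, t_rise=10.0, fall=300.0,
                 total=500.0):
    """Instant rise at t_rise, linear fall to rest over ``fall`` ms."""
    t = np.arange(0.0, total, dt)
    v = np.full_like(t, rest)
    on = t >= t_rise
    v[on] = peak - (peak - rest) * np.clip((t[on] - t_rise) / fall, 0, 1)
    return synthetic_trace(t, v=v, cai=1e-4 + 1e-4 * np.exp(-t / 50.0))


class TestAPBiomarkers:
    def test_trapezoid_closed_form(self):
        beat = trapezoid_ap()
        b = ap_biomarkers(beat)
        assert b.RMP == pytest.approx(-85.0)
        assert b.Vmax == pytest.approx(40.0, abs=0.25)
        assert b.APA == pytest.approx(125.0, abs=0.25)
        # ramp geometry: 90% repolarization reached 0.9*300 ms after the rise
        assert b.APD == pytest.approx(270.0, abs=1.0)
        # Tri = APD90 - APD40 = (0.9 - 0.4) * 300
        assert b.Tri == pytest.approx(150.0, abs=1.0)
        assert b.UPD < 2.0  # instant upstroke at the sampling limit

    def test_time_shift_invariance(self):
        beat = trapezoid_ap()
        shifted = synthetic_trace(beat.t + 137.0, v=beat.v, cai=beat.cai)
        b0, b1 = ap_biomarkers(beat), ap_biomarkers(shifted)
        assert b1.APD == pytest.approx(b0.APD, abs=1e-9)
        assert b1.Tri == pytest.approx(b0.Tri, abs=1e-9)

    def test_sampling_refinement(self):
        coarse = ap_biomarkers(trapezoid_ap(dt=1.0))
        fine = ap_biomarkers(trapezoid_ap(dt=0.5))
        assert fine.APD == pytest.approx(coarse.APD, abs=0.5)

    def test_non_captured_flagged_invalid(self):
        t = np.arange(0, 300.0, 0.5)
        beat = synthetic_trace(t, v=np.full_like(t, -85.0))
        assert not check_capture(beat)
        assert not ap_biomarkers(beat).valid


class TestCaTBiomarkers:
    def test_triangle_closed_form(self):
        dt = 0.5
        t = np.arange(0.0, 400.0, dt)
        base, peak = 1e-4, 1e-3
        rise = np.clip((t - 20.0) / 30.0, 0, 1)
        decay = np.clip((t - 50.0) / 300.0, 0, 1)
        ca = base + (peak - base) * np.where(t < 50.0, rise, 1 - decay)
        b = cat_biomarkers(synthetic_trace(t, cai=ca))
        assert b.CaTmax == pytest.approx(peak, rel=1e-3)
        assert b.CaTmin == pytest.approx(base, rel=1e-3)
        # take-off (10% up the rise: 3 ms after 20) to 90% decay
        # (90% down the fall: 270 ms after 50) -> 320 - 23 = 297 ms
        assert b.CaTD == pytest.approx(297.0, abs=1.0)

    def test_flat_transient_flagged(self):
        t = np.arange(0, 300.0, 0.5)
        b = cat_biomarkers(synthetic_trace(t, cai=np.full_like(t, 1e-4)))
        assert not b.cat_valid


class TestAlternansMagnitude:
    def _series(self, apds, cl=500.0):
        beats = []
        for apd in apds:
            beats.append(trapezoid_ap(fall=apd / 0.9, total=cl))
        return BeatSeries(cl=cl, beats=beats)

    def test_constant_series_is_zero(self):
        mags = alternans_magnitude(self._series([270, 270, 270, 270]))
        assert mags["dAPD"] == pytest.approx(0.0, abs=0.5)

    def test_alternating_series_arithmetic(self):
        mags = alternans_magnitude(self._series([280, 240, 280, 240]))
        assert mags["dAPD"] == pytest.approx(40.0, abs=1.0)

    def test_phase_invariance(self):
        a = alternans_magnitude(self._series([280, 240, 280, 240]))
        b = alternans_magnitude(self._series([240, 280, 240, 280]))
        assert a["dAPD"] == pytest.approx(b["dAPD"], abs=1e-9)

    def test_too_few_beats(self):
        with pytest.raises(ValueError):
            alternans_magnitude(self._series([270, 270]))

    def test_non_captured_beat_is_an_error(self):
        series = self._series([270, 270, 270, 270])
        flat = synthetic_trace(series[0].t, v=np.full(len(series[0]), -85.0))
        series.beats[2] = flat
        with pytest.raises(ValueError, match="non-captured"):
            alternans_magnitude(series)


class TestSimulatedBaseline:
    """Biomarkers on the real model (session-scoped paced beat)."""

    def test_baseline_biomarker_ranges(self, baseline_beat_cl1000):
        b = beat_biomarkers(baseline_beat_cl1000[0])
        # regression values from this implementation at CL 1000 ms; the
        # bands cover the physiological epicardial ranges
        assert 200.0 < b.APD < 260.0
        assert -91.0 < b.RMP < -85.0
        assert 25.0 < b.Vmax < 50.0
        assert b.APA == pytest.approx(b.Vmax - b.RMP, abs=1e-9)
        assert b.UPD < 3.0
        assert 3e-4 < b.CaTamp < 9e-4
        assert b.CaTmax > b.CaTmin > 0

    def test_beat_to_beat_stability(self, baseline_beat_cl1000):
        b0 = beat_biomarkers(baseline_beat_cl1000[0])
        b1 = beat_biomarkers(baseline_beat_cl1000[1])
        assert abs(b0.APD - b1.APD) < 1.0
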