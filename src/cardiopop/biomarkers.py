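"""Action-potential and calcium-transient biomarkers.

Nine per-beat biomarkers characterize each model: APD (at 90%
repolarization, the ORd convention), AP amplitude (APA), peak upstroke
voltage (Vmax), resting membrane potential (RMP), upstroke duration (UPD,
10%->90% of the upstroke), triangulation (Tri = APD90 - APD40), and the
calcium-transient systolic/diastolic levels and duration (CaTmax, CaTmin,
CaTD at 90% recovery).  Threshold crossings are linearly interpolated, so
biomarkers are sub-sample accurate and robust to refinement of the
sampling grid.

Alternans magnitude (dAPD, dCaT) is the mean absolute difference of the
biomarker between consecutive steady-state beats; it is invariant to the
(arbitrary) phase of the alternans.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trace import BeatSeries, BeatTrace

__all__ = [
    "BeatBiomarkers",
    "ap_biomarkers",
    "cat_biomarkers",
    "beat_biomarkers",
    "alternans_magnitude",
    "check_capture",
]


@dataclass
class BeatBiomarkers:
    APD: float = np.nan       # ms, at 90% repolarization
    APD40: float = np.nan     # ms, at 40% repolarization
    APA: float = np.nan       # mV
    Vmax: float = np.nan      # mV
    RMP: float = np.nan       # mV
    UPD: float = np.nan       # ms
    Tri: float = np.nan       # ms, APD90 - APD40
    CaTmax: float = np.nan    # mM
    CaTmin: float = np.nan    # mM
    CaTamp: float = np.nan    # mM
    CaTD: float = np.nan      # ms
    valid: bool = True        # AP captured and measurable
    cat_valid: bool = True    # calcium transient measurable (not flat)

    def as_dict(self):
        return {
            "APD": self.APD, "APA": self.APA, "Vmax": self.Vmax,
            "RMP": self.RMP, "UPD": self.UPD, "Tri": self.Tri,
            "CaTmax": self.CaTmax, "CaTmin": self.CaTmin,
            "CaTamp": self.CaTamp, "CaTD": self.CaTD, "valid": self.valid,
        }


def _cross_up(t, x, thr, lo, hi):
    """First upward crossing of thr in index window [lo, hi), interpolated."""
    for k in range(lo, min(hi, x.size) - 1):
        if x[k] < thr <= x[k + 1]:
            f = (thr - x[k]) / (x[k + 1] - x[k])
            return t[k] + f * (t[k + 1] - t[k])
    return np.nan


def _cross_down(t, x, thr, lo):
    """First downward crossing of thr at index >= lo, interpolated."""
    for k in range(lo, x.size - 1):
        if x[k] >= thr > x[k + 1]:
            f = (x[k] - thr) / (x[k] - x[k + 1])
            return t[k] + f * (t[k + 1] - t[k])
    return np.nan


def check_capture(beat: BeatTrace, window: float = 50.0) -> bool:
    """Captured iff peak Vm exceeds 0 mV within ``window`` ms of the stimulus."""
    sel = beat.t <= beat.t[0] + window
    return bool(np.max(beat.v[sel]) > 0.0)


def ap_biomarkers(beat: BeatTrace, repol_fraction: float = 0.9) -> BeatBiomarkers:
    """Voltage biomarkers of one beat (flagged invalid if not captured)."""
    b = BeatBiomarkers()
    if not check_capture(beat):
        b.valid = False
        return b
    t, v = beat.t, beat.v
    b.RMP = float(v[0])  # just before/at stimulus onset
    ipk = int(np.argmax(v))
    b.Vmax = float(v[ipk])
    b.APA = b.Vmax - b.RMP

    # activation = max dV/dt during the upstroke
    dvdt = np.gradient(v, t)
    iact = int(np.argmax(dvdt[: max(ipk + 1, 2)]))
    t_act = t[iact]

    t10 = _cross_up(t, v, b.RMP + 0.1 * b.APA, 0, ipk + 1)
    t90 = _cross_up(t, v, b.RMP + 0.9 * b.APA, 0, ipk + 1)
    b.UPD = t90 - t10

    thr90 = b.Vmax - repol_fraction * b.APA
    thr40 = b.Vmax - 0.4 * b.APA
    t_r90 = _cross_down(t, v, thr90, ipk)
    t_r40 = _cross_down(t, v, thr40, ipk)
    b.APD = t_r90 - t_act
    b.APD40 = t_r40 - t_act
    b.Tri = b.APD - b.APD40
    return b


def cat_biomarkers(beat: BeatTrace, recovery_fraction: float = 0.9,
                   out: BeatBiomarkers | None = None) -> BeatBiomarkers:
    """Calcium-transient biomarkers (flagged invalid on a flat transient)."""
    b = out if out is not None else BeatBiomarkers()
    t, ca = beat.t, beat.cai
    b.CaTmax = float(np.max(ca))
    b.CaTmin = float(np.min(ca))
    b.CaTamp = b.CaTmax - b.CaTmin
    if b.CaTamp < 1e-6:
        b.cat_valid = False
        return b
    ipk = int(np.argmax(ca))
    thr = b.CaTmin + (1.0 - recovery_fraction) * b.CaTamp
    t_off = _cross_up(t, ca, thr, 0, ipk + 1)
    if np.isnan(t_off):
        t_off = t[0]  # transient already above take-off at beat start
    t_rec = _cross_down(t, ca, thr, ipk)
    b.CaTD = t_rec - t_off
    return b


def beat_biomarkers(beat: BeatTrace) -> BeatBiomarkers:
    """All nine biomarkers for one beat."""
    b = ap_biomarkers(beat)
    if b.valid:
        cat_biomarkers(beat, out=b)
    return b


def alternans_magnitude(series: BeatSeries | list) -> dict:
    """Mean beat-to-beat |difference| of APD and CaT amplitude.

    Requires >= 4 captured steady-state beats; raises ``ValueError`` if any
    beat in the window failed 1:1 capture (alternans is undefined without
    capture).
    """
    beats = list(series)
    if len(beats) < 4:
        raise ValueError("need at least 4 beats to measure alternans")
    bm = [beat_biomarkers(b) for b in beats]
    if not all(x.valid for x in bm):
        raise ValueError("alternans undefined: non-captured beat in window")
    apds = np.array([x.APD for x in bm])
    camps = np.array([x.CaTamp for x in bm])
    cat_ok = all(x.cat_valid for x in bm)
    return {
        "dAPD": float(np.mean(np.abs(np.diff(apds)))),
        "dCaT": float(np.mean(np.abs(np.diff(camps)))) if cat_ok else np.nan,
        "APD_odd": float(np.mean(apds[1::2])),
        "APD_even": float(np.mean(apds[0::2])),
        "CaTamp_mean": float(np.mean(camps)),
    }
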