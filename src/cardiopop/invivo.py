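"""Synthetic stand-in for the in vivo activation-recovery-interval (ARI) data.

The original calibration data — epicardial sock-electrode unipolar
electrograms from patients paced at six cycle lengths — are not deposited.
This module emulates their two roles:

* :func:`generate_ari_study` draws a hierarchical synthetic ARI data set
  (patient effects + site effects + beat noise around a rate-dependent mean
  curve, with a fraction of alternans-susceptible sites carrying period-2
  ARI sequences) and derives per-CL APD calibration envelopes from the
  normal sites.
* :func:`synth_electrogram` / :func:`ari_extract` build toy unipolar
  electrograms with known activation/recovery times and extract ARI by the
  derivative rule (minimum derivative of the activation deflection to
  maximum derivative of the T-wave).

The default mean-ARI curve is anchored to the baseline epicardial model's
steady-state APD90 so that the baseline model is always inside the default
envelopes.  The electrogram morphology (two logistic deflections) is a
fixture exercising the extraction rule, not a physiological forward model.
All numbers drawn here are synthetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .population import CalibrationRanges
from .protocols import DEFAULT_CLS

__all__ = [
    "ARIGeneratorParams",
    "SyntheticARIStudy",
    "SyntheticElectrogram",
    "DEFAULT_MEAN_ARI",
    "generate_ari_study",
    "synth_electrogram",
    "ari_extract",
]

# Baseline epicardial model steady-state APD90 (ms) per CL, computed with
# this package's restitution protocol; used as the anchor of the synthetic
# mean-ARI curve (filled by scripts/freeze_baseline.py at build time and
# kept as plain constants).
DEFAULT_MEAN_ARI = {
    600.0: 211.0,
    550.0: 207.3,
    500.0: 203.6,
    450.0: 199.6,
    400.0: 195.1,
    350.0: 189.9,
}


@dataclass(frozen=True)
class ARIGeneratorParams:
    """Hierarchical generator parameters (all in ms except fractions).

    Between-patient and between-site standard deviations of 10-20 ms give
    aggregated ARI spreads of roughly +/-70 ms around the rate-dependence
    curve, the order seen in epicardial ARI maps, and produce min/max
    envelopes wide enough to admit a diverse calibrated population.
    """

    mean_ari: dict = field(default_factory=lambda: dict(DEFAULT_MEAN_ARI))
    patient_sd: float = 15.0
    site_sd: float = 10.0
    noise_sd: float = 3.0
    alternans_fraction: float = 0.1
    alternans_amp: float = 12.0
    n_beats: int = 8
    envelope_quantile: float = 0.0  # 0 -> min/max envelope

    def mean_at(self, cl: float) -> float:
        return float(self.mean_ari[float(cl)])


@dataclass
class SyntheticARIStudy:
    """Synthetic ARI samples and the calibration envelopes they imply."""

    table: pd.DataFrame           # patient, site, cl_ms, beat, ari_ms, alternans
    ranges: CalibrationRanges
    params: ARIGeneratorParams
    seed: int | None

    def to_csv(self, path):
        self.table.to_csv(path, index=False)


def generate_ari_study(cl_list=DEFAULT_CLS, n_sites: int = 240,
                       n_patients: int = 41,
                       params: ARIGeneratorParams | None = None,
                       seed: int | None = None) -> SyntheticARIStudy:
    """Draw a synthetic hierarchical ARI study.

    ARI(patient, site, CL, beat) = m(CL) + patient effect + site effect
    + beat noise (+/- half the alternans amplitude, alternating, on
    alternans-marked sites).  Calibration envelopes are the per-CL
    [min, max] of the site-mean ARIs over normal sites, clipped below the
    pacing CL (repolarization completes before the next beat).
    """
    p = params or ARIGeneratorParams()
    for cl in cl_list:
        if float(cl) not in p.mean_ari:
            raise KeyError(f"mean ARI curve has no value at CL={cl}")
    rng = np.random.default_rng(seed)
    pat_eff = rng.normal(0.0, 1.0, n_patients) * p.patient_sd
    site_eff = rng.normal(0.0, 1.0, (n_patients, n_sites)) * p.site_sd
    alt_site = rng.random((n_patients, n_sites)) < p.alternans_fraction
    rows = []
    for ip in range(n_patients):
        for isite in range(n_sites):
            for cl in cl_list:
                base = p.mean_at(cl) + pat_eff[ip] + site_eff[ip, isite]
                noise = rng.normal(0.0, 1.0, p.n_beats) * p.noise_sd
                ari = base + noise
                if alt_site[ip, isite]:
                    ari += 0.5 * p.alternans_amp * (-1.0) ** np.arange(p.n_beats)
                ari = np.clip(ari, 1.0, 0.95 * float(cl))
                for ib in range(p.n_beats):
                    rows.append((ip, isite, float(cl), ib, float(ari[ib]),
                                 bool(alt_site[ip, isite])))
    table = pd.DataFrame(rows, columns=["patient", "site", "cl_ms", "beat",
                                        "ari_ms", "alternans_site"])
    normal = table[~table.alternans_site]
    if normal.empty:  # degenerate request: every site alternans-marked
        normal = table
    site_means = (normal.groupby(["patient", "site", "cl_ms"])["ari_ms"]
                  .mean().reset_index())
    env = {}
    q = p.envelope_quantile
    for cl in cl_list:
        vals = site_means.loc[site_means.cl_ms == float(cl), "ari_ms"]
        lo = float(vals.quantile(q)) if q > 0 else float(vals.min())
        hi = float(vals.quantile(1 - q)) if q > 0 else float(vals.max())
        env[float(cl)] = (lo, min(hi, 0.95 * float(cl)))
    return SyntheticARIStudy(table=table, ranges=CalibrationRanges(env),
                             params=p, seed=seed)


# ---------------------------------------------------------------------------
# Toy unipolar electrograms
# ---------------------------------------------------------------------------

@dataclass
class SyntheticElectrogram:
    t: np.ndarray                 # ms
    v: np.ndarray                 # arbitrary units
    cl: float
    stimulus_times: np.ndarray
    activation_times: np.ndarray  # ground truth, per beat
    recovery_times: np.ndarray    # ground truth, per beat

    def to_csv(self, path):
        pd.DataFrame({"t_ms": self.t, "v": self.v}).to_csv(path, index=False)


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


def synth_electrogram(ari_sequence, cl: float, noise_sd: float = 0.0,
                      seed: int | None = None, sample_dt: float = 0.5,
                      activation_delay: float = 25.0,
                      dep_width: float = 1.5, twave_width: float = 6.0,
                      amplitude: float = 1.0) -> SyntheticElectrogram:
    """Build a toy unipolar electrogram encoding the given per-beat ARIs.

    Each beat is a steep negative logistic deflection centred at the
    activation time (minimum derivative there) followed by a slower
    positive-slope T-wave centred at activation + ARI (maximum derivative
    there), returning to baseline before the next stimulus.
    """
    ari = np.asarray(ari_sequence, dtype=float)
    if np.any(ari >= cl):
        raise ValueError("every ARI must be smaller than the cycle length")
    n_beats = ari.size
    t = np.arange(0.0, n_beats * cl, sample_dt)
    v = np.zeros_like(t)
    stim = np.arange(n_beats) * cl
    t_act = stim + activation_delay
    t_rec = t_act + ari
    for k in range(n_beats):
        v += -amplitude * _logistic((t - t_act[k]) / dep_width)
        v += amplitude * _logistic((t - t_rec[k]) / twave_width)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, noise_sd, v.size)
    return SyntheticElectrogram(t=t, v=v, cl=float(cl), stimulus_times=stim,
                                activation_times=t_act, recovery_times=t_rec)


def ari_extract(egm: SyntheticElectrogram, stimulus_times=None,
                dep_window: tuple = (0.0, 80.0),
                rep_window_start: float = 100.0) -> np.ndarray:
    """Per-beat ARI by the derivative rule.

    ARI = t(max dV/dt in the repolarization window) - t(min dV/dt in the
    depolarization window), windows referenced to each stimulus.  Beats
    with no measurable deflection (flat signal) are NaN.
    """
    stim = np.asarray(stimulus_times if stimulus_times is not None
                      else egm.stimulus_times, dtype=float)
    dt = egm.t[1] - egm.t[0]
    if dt > 1.0 + 1e-9:
        raise ValueError("electrogram sampling must be <= 1 ms")
    dv = np.gradient(egm.v, egm.t)
    # light smoothing of the derivative (~2.5 ms boxcar) stabilizes the
    # T-wave maximum-slope point against sample-level noise
    win = max(1, int(round(2.5 / dt)))
    if win > 1:
        kernel = np.ones(win) / win
        dv = np.convolve(dv, kernel, mode="same")
    scale = np.max(np.abs(dv)) if dv.size else 0.0
    out = np.full(stim.size, np.nan)
    for k, ts in enumerate(stim):
        cl = (stim[k + 1] - ts) if k + 1 < stim.size else egm.cl
        dep = (egm.t >= ts + dep_window[0]) & (egm.t <= ts + dep_window[1])
        rep = (egm.t >= ts + rep_window_start) & (egm.t < ts + cl)
        if not np.any(dep) or not np.any(rep):
            continue
        dmin = np.min(dv[dep])
        dmax = np.max(dv[rep])
        # measurable iff the deflections stand out from the overall signal
        if scale <= 0 or -dmin < 0.05 * scale or dmax < 0.005 * scale:
            continue
        t_act = egm.t[dep][np.argmin(dv[dep])]
        t_rec = egm.t[rep][np.argmax(dv[rep])]
        out[k] = t_rec - t_act
    return out
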