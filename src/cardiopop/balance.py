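"""Per-beat sarcoplasmic-reticulum and sarcolemmal calcium balances.

SRCB is the net Ca gained by the SR over one beat: the integral of SERCA
uptake minus RyR release.  In the ORd model J_up is referenced to NSR
volume and J_rel to JSR volume, so the two fluxes are volume-weighted
before subtraction; the result is expressed per litre of cytosol.  J_up is
the model's net pump flux (SERCA minus the NSR leak), which makes SRCB
exactly the per-beat change in total SR Ca content.

SCB is the net Ca gained by the whole cell across the sarcolemma over one
beat: the integral of all sarcolemmal Ca-carrying currents (I_CaL Ca
component, background Ca current, sarcolemmal Ca pump, and both Na/Ca
exchanger components at one Ca per elementary charge of exchanger
current), converted from A/F to molar flux with the cell capacitance and
Faraday's constant.  Sign convention for both: positive = net Ca gain.

At a period-1 steady state both balances vanish; during alternans two
consecutive beats carry balances of equal magnitude and opposite sign.
Units: umol per litre cytosol per beat.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ord import ACAP, FARADAY, VJSR, VMYO, VNSR
from .trace import BeatTrace

__all__ = [
    "srcb_per_beat",
    "scb_per_beat",
    "release_integral",
    "influx_integral",
    "series_balances",
    "balance_alternans_correlation",
]

_MM_TO_UM = 1.0e3


def _check_window(trace: BeatTrace, beat_window):
    if beat_window is None:
        return np.ones(trace.t.size, dtype=bool)
    lo, hi = beat_window
    if hi - lo < trace.t[-1] - trace.t[0] - 1e-9 and hi - lo < trace.dt:
        raise ValueError("beat window shorter than one sample")
    return (trace.t >= lo) & (trace.t < hi)


def srcb_per_beat(trace: BeatTrace, beat_window=None) -> float:
    """SR calcium balance of one beat (umol / L cytosol).

    Uses the integrator's exact per-beat flux integrals when the trace
    carries them (full-beat window only); otherwise trapezoid quadrature
    of the sampled fluxes.
    """
    if trace.flux_integrals is not None and beat_window is None:
        fi = trace.flux_integrals
        return (fi["Jup"] * VNSR - fi["Jrel"] * VJSR) / VMYO * _MM_TO_UM
    sel = _check_window(trace, beat_window)
    if trace.t[sel][-1] - trace.t[sel][0] < trace.t[-1] - trace.t[0] - 1e-9:
        raise ValueError("window must span the full beat")
    jup = trace.Jup[sel] * VNSR / VMYO
    jrel = trace.Jrel[sel] * VJSR / VMYO
    return float(np.trapezoid(jup - jrel, trace.t[sel])) * _MM_TO_UM


def release_integral(trace: BeatTrace) -> float:
    """Per-beat RyR release (umol / L cytosol); scale for the SRCB criterion."""
    if trace.flux_integrals is not None:
        return trace.flux_integrals["Jrel"] * VJSR / VMYO * _MM_TO_UM
    return float(np.trapezoid(trace.Jrel * VJSR / VMYO, trace.t)) * _MM_TO_UM


def _scb_from_currents(ical, icab, ipca, inaca):
    return (2.0 * inaca - ical - icab - ipca) * ACAP / (2.0 * FARADAY * VMYO)


def scb_per_beat(trace: BeatTrace, beat_window=None) -> float:
    """Sarcolemmal calcium balance of one beat (umol / L cytosol).

    Net influx rate (mM/ms, cytosol-referenced), from the model's own
    bookkeeping: ``(2*INaCa - ICaL - ICab - IpCa) * Acap / (2*F*Vmyo)``.
    The exchanger term carries one Ca per elementary charge (3 Na : 1 Ca).
    """
    if trace.flux_integrals is not None and beat_window is None:
        fi = trace.flux_integrals
        return float(_scb_from_currents(
            fi["ICaL"], fi["ICab"], fi["IpCa"],
            fi["INaCa_i"] + fi["INaCa_ss"])) * _MM_TO_UM
    sel = _check_window(trace, beat_window)
    rate = _scb_from_currents(trace.ICaL[sel], trace.ICab[sel],
                              trace.IpCa[sel], trace.inaca[sel])
    return float(np.trapezoid(rate, trace.t[sel])) * _MM_TO_UM


def influx_integral(trace: BeatTrace) -> float:
    """Per-beat Ca influx through I_CaL (umol / L cytosol); SCB criterion scale."""
    if trace.flux_integrals is not None:
        return -trace.flux_integrals["ICaL"] * ACAP \
            / (2.0 * FARADAY * VMYO) * _MM_TO_UM
    ical_in = np.minimum(trace.ICaL, 0.0)  # inward component
    rate = -ical_in * ACAP / (2.0 * FARADAY * VMYO)
    return float(np.trapezoid(rate, trace.t)) * _MM_TO_UM


def series_balances(series, model_id=None) -> pd.DataFrame:
    """Per-beat SRCB/SCB table for a recorded beat series at one CL.

    Beat parity (long/short APD) is attached so the short-APD beat of an
    alternating pair can be selected, as in the per-CL balance summaries.
    """
    from .biomarkers import beat_biomarkers  # local import, avoids cycle

    rows = []
    apds = [beat_biomarkers(b).APD for b in series]
    mean_apd = np.nanmean(apds)
    for k, beat in enumerate(series):
        rows.append({
            "model_id": model_id,
            "cl_ms": series.cl,
            "beat_index": k,
            "apd_ms": apds[k],
            "parity": "long" if apds[k] >= mean_apd else "short",
            "srcb_umol_per_l": srcb_per_beat(beat),
            "scb_umol_per_l": scb_per_beat(beat),
        })
    return pd.DataFrame(rows)


def balance_alternans_correlation(dapd_values, balance_values) -> float:
    """Pearson r between |balance| of the short-APD beat and dAPD.

    Requires >= 3 alternans models; raises ``ValueError`` otherwise.
    """
    from .stats import pearson

    dapd_values = np.asarray(dapd_values, dtype=float)
    balance_values = np.abs(np.asarray(balance_values, dtype=float))
    if dapd_values.size < 3:
        raise ValueError("correlation undefined with fewer than 3 models")
    return pearson(balance_values, dapd_values)
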