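"""Pacing, dynamic restitution, and action-potential-clamp protocols.

The restitution protocol paces each model at a descending ladder of cycle
lengths (default 600 -> 350 ms in 50 ms steps, optionally extended to
200 ms), with state carry-over from one CL to the next, mimicking an
in vivo step protocol.  At each CL a number of unrecorded pre-beats settles
the model onto its (period-1 or period-2) attractor before recorded beats
are analyzed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import ord
from .biomarkers import alternans_magnitude, beat_biomarkers, check_capture
from .classification import RestitutionResult
from .engine import (PREBEAT_SCHEDULE, RECORD_SCHEDULE, SolverError, Stimulus,
                     run_clamped, run_paced)
from .trace import BeatSeries, split_record

__all__ = [
    "PacingProtocol",
    "DEFAULT_CLS",
    "FAST_EXTENSION_CLS",
    "pace",
    "run_restitution",
    "ap_clamp",
    "check_capture",
]

DEFAULT_CLS = (600.0, 550.0, 500.0, 450.0, 400.0, 350.0)
FAST_EXTENSION_CLS = (300.0, 250.0, 200.0)


@dataclass(frozen=True)
class PacingProtocol:
    """Steady-state pacing protocol over a ladder of cycle lengths."""

    cl_list: tuple = DEFAULT_CLS
    n_prebeats: int = 500
    n_record: int = 4
    carryover: bool = True
    stimulus: Stimulus = field(default_factory=Stimulus)

    def __post_init__(self):
        if self.n_record < 4 or self.n_record % 2:
            raise ValueError("n_record must be >= 4 and even")
        if min(self.cl_list) < 200.0:
            raise ValueError("cycle lengths below 200 ms are not supported")

    def extended(self, cls=FAST_EXTENSION_CLS) -> "PacingProtocol":
        return PacingProtocol(tuple(self.cl_list) + tuple(cls),
                              self.n_prebeats, self.n_record,
                              self.carryover, self.stimulus)


def pace(spec, cl, n_prebeats, n_record, initial_state=None,
         stimulus=None, schedule=None, prebeat_schedule=None) -> BeatSeries:
    """Pace at one CL; returns the last ``n_record`` beats plus final state."""
    if cl < 200.0:
        raise ValueError("cl must be >= 200 ms")
    if n_prebeats < 0 or n_record < 0:
        raise ValueError("beat counts must be non-negative")
    y0 = initial_state if initial_state is not None else ord.initial_state()
    rec, integ, y = run_paced(spec, y0, float(cl), int(n_prebeats),
                              int(n_record), stimulus=stimulus,
                              schedule=schedule or RECORD_SCHEDULE,
                              prebeat_schedule=prebeat_schedule or PREBEAT_SCHEDULE)
    sample_dt = (schedule or RECORD_SCHEDULE).sample_dt
    beats = split_record(rec, cl, sample_dt, integ) if n_record > 0 else []
    return BeatSeries(cl=float(cl), beats=beats, final_state=y)


def run_restitution(spec, protocol: PacingProtocol, initial_state=None,
                    apd_ranges=None, keep_series=False) -> RestitutionResult:
    """Steady-state (dynamic) restitution over the protocol's CL ladder.

    Per CL: odd/even-beat APD means, alternans magnitudes dAPD and dCaT,
    mean diastolic interval (DI = CL - APD90 of the preceding beat) and a
    capture flag.  On loss of 1:1 capture, that CL is marked uncaptured and
    its quantities are NaN.

    ``apd_ranges``: optional mapping cl -> (lower, upper) APD bounds.  When
    given, the ladder stops at the first CL whose mean steady-state APD
    violates its bounds (or that loses capture); the returned result has
    ``rejected_at`` set to that CL.  This is the calibration fast path —
    models rejected at the first CL skip the remaining five.

    ``keep_series=True`` attaches the recorded BeatSeries per CL
    (``result.series[cl]``) so balance analyses can reuse the very beats
    the restitution metrics were measured on.
    """
    state = initial_state if initial_state is not None else ord.initial_state()
    n_cl = len(protocol.cl_list)
    apd_odd = np.full(n_cl, np.nan)
    apd_even = np.full(n_cl, np.nan)
    dapd = np.full(n_cl, np.nan)
    dcat = np.full(n_cl, np.nan)
    catamp = np.full(n_cl, np.nan)
    mean_di = np.full(n_cl, np.nan)
    captured = np.zeros(n_cl, dtype=bool)
    per_cl_biomarkers = []
    rejected_at = None
    series_by_cl = {}

    for k, cl in enumerate(protocol.cl_list):
        try:
            series = pace(spec, cl, protocol.n_prebeats, protocol.n_record,
                          initial_state=state, stimulus=protocol.stimulus)
        except SolverError as err:
            raise SolverError(f"model failed at CL={cl}: {err}") from err
        if protocol.carryover:
            state = series.final_state
        if keep_series:
            series_by_cl[float(cl)] = series
        cap = [check_capture(b) for b in series]
        per_cl_biomarkers.append(beat_biomarkers(series[0]) if cap[0] else None)
        if not all(cap):
            if apd_ranges is not None and cl in apd_ranges:
                rejected_at = cl
                break
            continue
        captured[k] = True
        mags = alternans_magnitude(series)
        apd_odd[k] = mags["APD_odd"]
        apd_even[k] = mags["APD_even"]
        dapd[k] = mags["dAPD"]
        dcat[k] = mags["dCaT"]
        catamp[k] = mags["CaTamp_mean"]
        apds = np.array([beat_biomarkers(b).APD for b in series])
        mean_di[k] = float(np.mean(cl - apds[:-1]))
        if apd_ranges is not None and cl in apd_ranges:
            lo, hi = apd_ranges[cl]
            apd = 0.5 * (apd_odd[k] + apd_even[k])
            if not (lo <= apd <= hi):
                rejected_at = cl
                break

    while len(per_cl_biomarkers) < n_cl:
        per_cl_biomarkers.append(None)

    return RestitutionResult(
        cls=np.asarray(protocol.cl_list, dtype=float),
        apd_odd=apd_odd, apd_even=apd_even, dapd=dapd, dcat=dcat,
        catamp_mean=catamp, mean_di=mean_di, captured=captured,
        biomarkers=per_cl_biomarkers, rejected_at=rejected_at,
        series=series_by_cl if keep_series else None,
    )


def ap_clamp(spec, vm_waveform, n_beats, initial_state=None,
             sample_dt=0.5, n_preperiods: int = 0) -> BeatSeries:
    """Clamp Vm to a command waveform; calcium states evolve freely.

    ``vm_waveform``: one period of the command (sampled at ``sample_dt``,
    must be <= 1 ms).  The waveform may contain several beats (e.g. a
    long+long pair); ``n_beats`` counts repetitions of the whole waveform.
    """
    if sample_dt > 1.0:
        raise ValueError("clamp waveform sampling must be <= 1 ms")
    y0 = initial_state if initial_state is not None else ord.initial_state()
    vcmd = np.asarray(vm_waveform, dtype=float)
    if n_preperiods > 0:
        _, y0 = run_clamped(spec, y0, vcmd, n_preperiods, sample_dt=sample_dt)
    rec, y = run_clamped(spec, y0, vcmd, int(n_beats), sample_dt=sample_dt)
    period = vcmd.size * sample_dt
    beats = split_record(rec, period, sample_dt)
    return BeatSeries(cl=period, beats=beats, final_state=y)
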