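"""Shared fixtures.

Simulation fixtures are session-scoped: the paced baseline beat and the
small study population are computed once and reused by the biomarker,
balance, protocol and acceptance tests.  Sizes are scaled down relative to
a full study (documented in the methods note) so the whole suite runs on
one CPU in minutes.
"""

from __future__ import annotations

import numpy as np
import pytest

from cardiopop import build_model, initial_state
from cardiopop.protocols import PacingProtocol, pace
from cardiopop.trace import BeatTrace
from cardiopop.engine import N_REC, REC

# scaled-down protocol used throughout the suite: 150 pre-beats with state
# carry-over from the packaged paced steady state settles period-1 and
# period-2 attractors to sub-ms APD accuracy (asserted by the convergence
# test in test_protocols.py)
FAST_PREBEATS = 150


@pytest.fixture(scope="session")
def baseline_spec():
    return build_model()


@pytest.fixture(scope="session")
def baseline_state():
    return initial_state(paced=True)


@pytest.fixture(scope="session")
def baseline_beat_cl1000(baseline_spec, baseline_state):
    """One steady-state baseline beat at CL 1000 ms."""
    series = pace(baseline_spec, 1000.0, 20, 2, initial_state=baseline_state)
    return series


@pytest.fixture(scope="session")
def baseline_restitution_series(baseline_spec, baseline_state):
    """Baseline beats at each protocol CL (carry-over), 4 recorded beats."""
    out = {}
    state = baseline_state
    for cl in (600.0, 500.0, 350.0):
        series = pace(baseline_spec, cl, FAST_PREBEATS, 4, initial_state=state)
        state = series.final_state
        out[cl] = series
    return out


def synthetic_trace(t, v=None, cai=None, **channels) -> BeatTrace:
    """Build a BeatTrace with only the named channels non-zero."""
    t = np.asarray(t, dtype=float)
    data = np.zeros((t.size, N_REC))
    if v is not None:
        data[:, REC["v"]] = v
    if cai is not None:
        data[:, REC["cai"]] = cai
    for name, values in channels.items():
        data[:, REC[name]] = values
    return BeatTrace(t, data)
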