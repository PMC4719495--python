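"""Beat-level containers for simulated traces.

A :class:`BeatTrace` holds one paced beat sampled on a uniform grid
(default 0.5 ms), with membrane potential, the calcium-handling state and
every sarcolemmal Ca-carrying current.  A :class:`BeatSeries` is a list of
contiguous beats at one cycle length plus the final model state, so pacing
can be resumed (state carry-over between cycle lengths).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import N_REC, REC, REC_NAMES

# CSV/HDF5 column names (units spelled out once, here)
_EXPORT_COLS = {
    "t": "t_ms",
    "v": "Vm_mV",
    "cai": "Cai_mM",
    "cass": "Cass_mM",
    "cansr": "CaNSR_mM",
    "cajsr": "CaJSR_mM",
    "nai": "Nai_mM",
    "Jrel": "Jrel_mM_per_ms",
    "Jup": "Jup_mM_per_ms",
    "Jleak": "Jleak_mM_per_ms",
    "Jtr": "Jtr_mM_per_ms",
    "Jdiff": "Jdiff_mM_per_ms",
    "ICaL": "ICaL_A_per_F",
    "ICaNa": "ICaNa_A_per_F",
    "ICaK": "ICaK_A_per_F",
    "INaCa_i": "INaCa_i_A_per_F",
    "INaCa_ss": "INaCa_ss_A_per_F",
    "ICab": "ICab_A_per_F",
    "IpCa": "IpCa_A_per_F",
    "stim": "stim_flag",
}


@dataclass
class BeatTrace:
    """One beat: time (ms, 0 = stimulus onset) and recorded channels.

    ``flux_integrals`` (if present) are the per-beat time-integrals of the
    Ca-carrying currents and SR fluxes accumulated by the integrator at
    sub-step resolution; the balance module prefers them over re-integrating
    the sampled trace.
    """

    t: np.ndarray
    data: np.ndarray  # shape (n_samples, N_REC)
    flux_integrals: dict | None = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != N_REC:
            raise ValueError("data must have one column per recorded channel")
        if self.t.size != self.data.shape[0]:
            raise ValueError("time and channel arrays must have equal length")
        if self.t.size >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ValueError("time must be strictly increasing")
            if np.max(dt) > 1.0 + 1e-9:
                raise ValueError("sampling interval must be <= 1 ms")

    def __getattr__(self, name):
        try:
            return self.data[:, REC[name]]
        except KeyError:
            raise AttributeError(name) from None

    def __len__(self):
        return self.t.size

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def inaca(self) -> np.ndarray:
        """Total Na/Ca exchanger current (bulk + subspace components, A/F)."""
        return self.data[:, REC["INaCa_i"]] + self.data[:, REC["INaCa_ss"]]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.data, columns=list(REC_NAMES))
        df.insert(0, "t", self.t)
        return df.rename(columns=_EXPORT_COLS)

    def to_csv(self, path):
        self.to_dataframe().to_csv(path, index=False)

    def to_hdf5(self, group):
        """Write named datasets into an open h5py group."""
        df = self.to_dataframe()
        for col in df.columns:
            group.create_dataset(col, data=df[col].to_numpy())


@dataclass
class BeatSeries:
    """Contiguous recorded beats at one cycle length, plus carry-over state."""

    cl: float
    beats: list = field(default_factory=list)
    final_state: np.ndarray | None = None

    def __len__(self):
        return len(self.beats)

    def __iter__(self):
        return iter(self.beats)

    def __getitem__(self, k):
        return self.beats[k]


def split_record(rec: np.ndarray, cl: float, sample_dt: float = 0.5,
                 integ=None):
    """Split a raw engine record into per-beat traces (t = 0 at stimulus)."""
    from .engine import INTEG_NAMES

    nsamp = int(round(cl / sample_dt))
    if rec.shape[0] % nsamp:
        raise ValueError("record length is not a whole number of beats")
    n_beats = rec.shape[0] // nsamp
    t = np.arange(nsamp) * sample_dt
    beats = []
    for k in range(n_beats):
        fi = (dict(zip(INTEG_NAMES, integ[k])) if integ is not None else None)
        beats.append(BeatTrace(t, rec[k * nsamp:(k + 1) * nsamp],
                               flux_integrals=fi))
    return beats
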