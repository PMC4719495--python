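"""Alternans classification: normal, Eye-type, Fork-type, or CaT-only.

Eye-type restitution is a closed bifurcation: APD alternans appear as the
pacing rate increases and vanish again at the fastest rates.  Fork-type is
an open bifurcation: alternans persist at the fastest captured rate.
Models whose APD alternans stay below threshold but whose calcium
transient alternates are CaT-only.  The onset cycle length is the longest
CL with above-threshold APD alternans.

Classification is evaluated on the fastest *captured* CL, so 2:1 block at
very fast pacing cannot spuriously close a fork.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RestitutionResult",
    "AlternansClass",
    "APD_ALTERNANS_THRESHOLD",
    "CAT_ALTERNANS_REL_THRESHOLD",
    "classify",
    "onset_cl",
]

# an APD-alternans model has dAPD >= 5 ms at some CL (the boundary used to
# separate CaT-only models); the CaT threshold is relative to mean CaT
# amplitude since no absolute value is established for the model population
APD_ALTERNANS_THRESHOLD = 5.0      # ms
CAT_ALTERNANS_REL_THRESHOLD = 0.05  # fraction of mean CaT amplitude


@dataclass
class RestitutionResult:
    """Per-CL steady-state restitution summary for one model."""

    cls: np.ndarray                 # cycle lengths, ms (descending)
    apd_odd: np.ndarray             # ms
    apd_even: np.ndarray            # ms
    dapd: np.ndarray                # ms
    dcat: np.ndarray                # mM
    catamp_mean: np.ndarray         # mM
    mean_di: np.ndarray             # ms
    captured: np.ndarray            # bool
    biomarkers: list = field(default_factory=list)  # per-CL BeatBiomarkers
    rejected_at: float | None = None  # CL at which calibration stopped, if any
    series: dict | None = None        # cl -> recorded BeatSeries (optional)

    def __post_init__(self):
        n = len(self.cls)
        for name in ("apd_odd", "apd_even", "dapd", "dcat",
                     "catamp_mean", "mean_di", "captured"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n,):
                raise ValueError(f"{name} must match the CL grid")
            setattr(self, name, arr)
        if np.any(self.dapd[self.captured] < 0):
            raise ValueError("dAPD must be non-negative")

    @property
    def apd_mean(self) -> np.ndarray:
        return 0.5 * (self.apd_odd + self.apd_even)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cl_ms": self.cls,
            "apd_odd_ms": self.apd_odd,
            "apd_even_ms": self.apd_even,
            "dapd_ms": self.dapd,
            "dcat_mM": self.dcat,
            "catamp_mean_mM": self.catamp_mean,
            "mean_di_ms": self.mean_di,
            "captured": self.captured,
        })


@dataclass(frozen=True)
class AlternansClass:
    label: str                 # normal | eye | fork | cat_only
    onset_cl: float | None = None

    def __post_init__(self):
        if self.label not in ("normal", "eye", "fork", "cat_only"):
            raise ValueError(f"unknown label {self.label!r}")
        if (self.onset_cl is not None) != (self.label in ("eye", "fork")):
            raise ValueError("onset_cl defined iff label is eye or fork")


def classify(r: RestitutionResult,
             apd_thresh: float = APD_ALTERNANS_THRESHOLD,
             cat_thresh: float | None = None) -> AlternansClass:
    """Classify one model's restitution behaviour.

    ``cat_thresh`` is an absolute dCaT threshold (mM); if None it defaults
    to ``CAT_ALTERNANS_REL_THRESHOLD`` x the model's mean CaT amplitude,
    evaluated per CL.
    """
    cap = np.asarray(r.captured, dtype=bool)
    if not np.any(cap):
        raise ValueError("no captured CL: classification undefined")
    dapd = r.dapd[cap]
    has_apd_alt = dapd >= apd_thresh
    if np.any(has_apd_alt):
        fastest = np.argmin(r.cls[cap])  # fastest *captured* CL
        label = "fork" if has_apd_alt[fastest] else "eye"
        return AlternansClass(label, onset_cl=onset_cl_value(r, apd_thresh))
    if cat_thresh is None:
        thr = CAT_ALTERNANS_REL_THRESHOLD * r.catamp_mean[cap]
    else:
        thr = np.full(dapd.shape, float(cat_thresh))
    if np.any(r.dcat[cap] >= thr):
        return AlternansClass("cat_only")
    return AlternansClass("normal")


def onset_cl_value(r: RestitutionResult,
                   thresh: float = APD_ALTERNANS_THRESHOLD) -> float:
    """Longest CL with dAPD >= thresh (alternans-onset CL)."""
    cap = np.asarray(r.captured, dtype=bool)
    qualifying = r.cls[cap][r.dapd[cap] >= thresh]
    if qualifying.size == 0:
        raise ValueError("no CL meets the alternans threshold")
    return float(np.max(qualifying))


# spec-facing alias: operate on a classified model
def onset_cl(r: RestitutionResult,
             thresh: float = APD_ALTERNANS_THRESHOLD) -> float:
    return onset_cl_value(r, thresh)
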