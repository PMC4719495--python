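"""Latin-Hypercube population generation, evaluation and calibration.

The experimentally calibrated population design: draw N parameter-scaling
vectors over [0, 2]^11 by Latin Hypercube Sampling (one sample per
equal-width stratum per dimension), run each variant through the dynamic
restitution protocol, and accept the models whose mean steady-state APD
lies within per-CL envelopes derived from (in vivo or synthetic)
activation-recovery-interval data — a min/max envelope calibration.

Evaluation fuses calibration with the CL ladder: since CLs are traversed
long -> short with state carry-over, a model whose APD violates its
envelope at the first CL is rejected without simulating the remaining
five.  Rejection records the first violated CL; failed integrations are
recorded as rejected with a reason, never dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from scipy.stats import qmc

from .classification import classify, onset_cl_value
from .engine import SolverError
from .ord import SCALING_NAMES, ParameterScaling, build_model
from .protocols import PacingProtocol, run_restitution

__all__ = [
    "CalibrationRanges",
    "lhs_sample",
    "evaluate_population",
    "calibrate",
    "classify_population",
]


@dataclass(frozen=True)
class CalibrationRanges:
    """Per-CL [lower, upper] APD envelopes (ms)."""

    ranges: dict  # cl (float) -> (lo, hi)

    def __post_init__(self):
        for cl, (lo, hi) in self.ranges.items():
            if not lo <= hi:  # point envelopes (lo == hi) are allowed
                raise ValueError(f"empty envelope at CL={cl}: [{lo}, {hi}]")

    def __getitem__(self, cl):
        return self.ranges[float(cl)]

    def __contains__(self, cl):
        return float(cl) in self.ranges

    def require(self, cl_list):
        missing = [cl for cl in cl_list if float(cl) not in self.ranges]
        if missing:
            raise KeyError(f"no calibration range for CLs {missing}")

    def accepts(self, cl, apd) -> bool:
        lo, hi = self.ranges[float(cl)]
        return bool(lo <= apd <= hi) and np.isfinite(apd)

    def to_frame(self) -> pd.DataFrame:
        cls = sorted(self.ranges, reverse=True)
        return pd.DataFrame({
            "cl_ms": cls,
            "apd_lower_ms": [self.ranges[c][0] for c in cls],
            "apd_upper_ms": [self.ranges[c][1] for c in cls],
        })

    def to_yaml(self, path):
        payload = {float(cl): [float(lo), float(hi)]
                   for cl, (lo, hi) in self.ranges.items()}
        with open(path, "w") as fh:
            yaml.safe_dump({"apd_ranges_ms": payload}, fh)

    @classmethod
    def from_yaml(cls, path) -> "CalibrationRanges":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls({float(k): tuple(map(float, v))
                    for k, v in payload["apd_ranges_ms"].items()})


def lhs_sample(n: int, low: float = 0.0, high: float = 2.0,
               n_params: int = len(SCALING_NAMES),
               seed: int | None = None) -> np.ndarray:
    """Latin Hypercube sample of scaling factors: shape (n, n_params).

    One point per equal-width stratum in every dimension; deterministic
    under a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    sampler = qmc.LatinHypercube(d=n_params, seed=seed)
    unit = sampler.random(n)
    return qmc.scale(unit, [low] * n_params, [high] * n_params)


def _row_template(model_id, factors):
    row = {"model_id": model_id}
    row.update({name: factors[k] for k, name in enumerate(SCALING_NAMES)})
    return row


_BIO_COLS = ("APA", "Vmax", "RMP", "UPD", "Tri",
             "CaTmax", "CaTmin", "CaTamp", "CaTD")


def evaluate_population(samples, protocol: PacingProtocol,
                        ranges: CalibrationRanges | None = None,
                        initial_state=None,
                        progress: bool = False) -> pd.DataFrame:
    """Run every parameter sample through the restitution protocol.

    Returns the population table: one row per model with its scaling
    factors, per-CL biomarkers (columns suffixed ``_<cl>``), and — when
    ``ranges`` is given — the calibration verdict and first-violated CL.
    Integration failures are recorded (verdict "rejected", reason
    "solver_failure"), never silently dropped.
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if samples.size == 0:
        samples = samples.reshape(0, len(SCALING_NAMES))
    if ranges is not None:
        ranges.require(protocol.cl_list)
    apd_ranges = ({float(cl): ranges[cl] for cl in protocol.cl_list}
                  if ranges is not None else None)
    rows = []
    for mid, factors in enumerate(samples):
        row = _row_template(mid, factors)
        try:
            scaling = ParameterScaling.from_array(factors)
            spec = build_model(scaling)
            res = run_restitution(spec, protocol, initial_state=initial_state,
                                  apd_ranges=apd_ranges)
        except SolverError as err:
            row["verdict"] = "rejected"
            row["reject_reason"] = f"solver_failure: {err}"
            rows.append(row)
            continue
        for k, cl in enumerate(protocol.cl_list):
            suf = f"_{int(cl)}"
            row[f"apd{suf}"] = 0.5 * (res.apd_odd[k] + res.apd_even[k])
            row[f"dapd{suf}"] = res.dapd[k]
            row[f"dcat{suf}"] = res.dcat[k]
            row[f"catamp{suf}"] = res.catamp_mean[k]
            row[f"di{suf}"] = res.mean_di[k]
            row[f"captured{suf}"] = bool(res.captured[k])
            bio = res.biomarkers[k]
            for name in _BIO_COLS:
                row[f"{name}{suf}"] = getattr(bio, name) if bio else np.nan
        if ranges is not None:
            if res.rejected_at is None:
                row["verdict"] = "accepted"
                row["reject_reason"] = ""
            else:
                row["verdict"] = "rejected"
                row["reject_reason"] = f"apd_out_of_range@{int(res.rejected_at)}"
        if res.rejected_at is None:
            # classification only meaningful on fully evaluated models
            try:
                cls = classify(res)
                row["label"] = cls.label
                row["onset_cl"] = cls.onset_cl
            except ValueError:
                row["label"] = "unclassified"
                row["onset_cl"] = None
        rows.append(row)
        if progress:
            print(f"model {mid}: {row.get('verdict', 'evaluated')} "
                  f"{row.get('label', '')}", flush=True)
    table = pd.DataFrame(rows)
    if table.empty:
        table = pd.DataFrame(columns=["model_id", *SCALING_NAMES])
    return table


def calibrate(table: pd.DataFrame, ranges: CalibrationRanges,
              cl_list=None) -> pd.DataFrame:
    """Fill calibration verdicts on an evaluated population table.

    Accepted iff the mean steady-state APD lies within the envelope at
    every CL; the rejection reason records the first violated CL
    (long -> short order).  Raises ``KeyError`` if a CL lacks an envelope.
    """
    if cl_list is None:
        cl_list = sorted({float(c.split("_")[1]) for c in table.columns
                          if c.startswith("apd_")}, reverse=True)
    ranges.require(cl_list)
    out = table.copy()
    verdicts, reasons = [], []
    for _, row in out.iterrows():
        verdict, reason = "accepted", ""
        if str(row.get("reject_reason", "")).startswith("solver_failure"):
            verdict, reason = "rejected", row["reject_reason"]
        else:
            for cl in cl_list:
                apd = row.get(f"apd_{int(cl)}", np.nan)
                if not ranges.accepts(cl, apd):
                    verdict = "rejected"
                    reason = f"apd_out_of_range@{int(cl)}"
                    break
        verdicts.append(verdict)
        reasons.append(reason)
    out["verdict"] = verdicts
    out["reject_reason"] = reasons
    return out


def classify_population(table: pd.DataFrame) -> pd.DataFrame:
    """Summary counts of alternans classes among accepted models."""
    acc = table[table.get("verdict", "accepted") == "accepted"]
    return acc.groupby("label", dropna=False).size().rename("count").reset_index()
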