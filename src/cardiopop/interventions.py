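"""Intervention studies: Na/Ca-exchanger block and I_CaL kinetics variation.

The exchanger-block study rescales the Na/Ca exchanger conductance of
previously classified alternans models by (1 - f) for block fractions
f in {0.2, 0.4, 0.6}, re-runs the restitution protocol and re-classifies,
reporting the fraction of models per class and the change in calcium
balances.  Because the block is applied on top of the model's own
(typically enhanced) exchanger conductance, the product can leave the
population's nominal [0, 2] sampling range only downwards, never upwards.

The kinetics study varies one I_CaL time constant at a time — activation
(tau_d), inactivation (tau_f) or recovery from Ca-dependent inactivation
(tau_j) — over multipliers {0.5, 0.75, 1.0, 1.25, 1.5}, measures APD
alternans magnitude and the |SCB| and |SRCB| of the short-APD beat at a
chosen CL, and reports the linear fit of dAPD against each balance.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .balance import scb_per_beat, srcb_per_beat
from .biomarkers import beat_biomarkers
from .classification import classify
from .ord import KineticsScaling, ModelSpec, ParameterScaling, build_model
from .protocols import PacingProtocol, pace, run_restitution

__all__ = [
    "DEFAULT_BLOCK_FRACTIONS",
    "KINETICS_MULTIPLIERS",
    "inaca_block_study",
    "ical_kinetics_study",
    "alternans_balances",
]

DEFAULT_BLOCK_FRACTIONS = (0.2, 0.4, 0.6)
KINETICS_MULTIPLIERS = (0.5, 0.75, 1.0, 1.25, 1.5)
_TAU_FIELDS = {"tau_d": "m_tau_d", "tau_f": "m_tau_f", "tau_j": "m_tau_j"}


def _blocked_spec(spec: ModelSpec, fraction: float) -> ModelSpec:
    if not 0.0 <= fraction < 1.0:
        raise ValueError("block fraction must be in [0, 1)")
    s = spec.scaling
    blocked = replace(s, s_GNaCa=s.s_GNaCa * (1.0 - fraction))
    return ModelSpec(scaling=blocked, kinetics=spec.kinetics)


def alternans_balances(spec: ModelSpec, cl: float, protocol: PacingProtocol,
                       initial_state=None) -> dict:
    """dAPD and short-beat |SRCB|, |SCB| at one CL (steady state).

    The target CL is approached through the protocol's descending ladder
    (capped at the two next-longer CLs) so the model lands on the same
    attractor a full restitution run reaches; jumping straight from the
    slow-rate steady state can leave a period-2 attractor undeveloped
    within the pre-beat budget.
    """
    state = initial_state
    if state is None:
        warmup = [c for c in protocol.cl_list if c > cl][-2:]
        for c in warmup:
            s = pace(spec, c, protocol.n_prebeats, 0,
                     stimulus=protocol.stimulus, initial_state=state)
            state = s.final_state
    series = pace(spec, cl, protocol.n_prebeats, max(protocol.n_record, 4),
                  initial_state=state, stimulus=protocol.stimulus)
    apds = np.array([beat_biomarkers(b).APD for b in series])
    dapd = float(np.mean(np.abs(np.diff(apds))))
    short = int(np.argmin(apds[:2]))
    return {
        "dapd": dapd,
        "srcb": srcb_per_beat(series[short]),
        "scb": scb_per_beat(series[short]),
        "srcb_pair": (srcb_per_beat(series[short]),
                      srcb_per_beat(series[1 - short])),
        "scb_pair": (scb_per_beat(series[short]),
                     scb_per_beat(series[1 - short])),
    }


def inaca_block_study(alternans_models, protocol: PacingProtocol,
                      block_fractions=DEFAULT_BLOCK_FRACTIONS,
                      balance_cl: float | None = None,
                      include_baseline: bool = True) -> pd.DataFrame:
    """Exchanger-block intervention over a set of classified alternans models.

    ``alternans_models``: iterable of ``(model_id, ParameterScaling, label)``
    with label in {eye, fork, cat_only}.  Returns one row per model x
    condition (including the untreated f=0 baseline unless
    ``include_baseline`` is False) with the post-block class and, when
    ``balance_cl`` is given, balance magnitudes at that CL.
    """
    rows = []
    for mid, scaling, label in alternans_models:
        if label not in ("eye", "fork", "cat_only"):
            raise ValueError(f"model {mid} is not an alternans model ({label})")
        fractions = (0.0, *block_fractions) if include_baseline \
            else tuple(block_fractions)
        for f in fractions:
            spec = _blocked_spec(build_model(scaling), f)
            res = run_restitution(spec, protocol)
            cls = classify(res)
            row = {
                "model_id": mid,
                "pre_label": label,
                "condition": f"inaca_block_{f:.2f}",
                "block_fraction": f,
                "post_label": cls.label,
                "post_onset_cl": cls.onset_cl,
                "max_dapd": float(np.nanmax(res.dapd)),
            }
            if balance_cl is not None:
                k = list(res.cls).index(float(balance_cl))
                if res.captured[k]:
                    bal = alternans_balances(spec, balance_cl, protocol)
                    row["srcb_abs"] = abs(bal["srcb"])
                    row["scb_abs"] = abs(bal["scb"])
            rows.append(row)
    return pd.DataFrame(rows)


def block_conversion_summary(result: pd.DataFrame) -> pd.DataFrame:
    """Percent of models per post-block class, per block fraction.

    Reported twice: over APD-alternans models only (eye+fork, the strict
    reading of "APD alternans models") and over all alternans models
    including CaT-only.
    """
    out = []
    for f, grp in result.groupby("block_fraction"):
        apd_grp = grp[grp.pre_label.isin(["eye", "fork"])]
        for name, g in (("apd_alternans", apd_grp), ("all_alternans", grp)):
            n = len(g)
            if n == 0:
                continue
            for label in ("normal", "eye", "fork", "cat_only"):
                out.append({
                    "block_fraction": f,
                    "denominator": name,
                    "post_label": label,
                    "percent": 100.0 * float((g.post_label == label).sum()) / n,
                    "n": n,
                })
    return pd.DataFrame(out)


def ical_kinetics_study(scaling: ParameterScaling, cl: float,
                        protocol: PacingProtocol,
                        multipliers=KINETICS_MULTIPLIERS,
                        model_id=None) -> pd.DataFrame:
    """One-at-a-time I_CaL time-constant variation at a fixed CL.

    Returns one row per condition (tau x multiplier, plus the shared
    untreated condition) with dAPD and short-beat |SRCB|, |SCB|.
    """
    for m in multipliers:
        if not 0.5 <= m <= 1.5:
            raise ValueError(f"multiplier {m} outside [0.5, 1.5]")
    rows = []
    base = alternans_balances(build_model(scaling), cl, protocol)
    rows.append({"model_id": model_id, "condition": "original",
                 "tau": "none", "multiplier": 1.0,
                 "dapd": base["dapd"], "srcb_abs": abs(base["srcb"]),
                 "scb_abs": abs(base["scb"])})
    for tau, fieldname in _TAU_FIELDS.items():
        for m in multipliers:
            if m == 1.0:
                continue
            kin = KineticsScaling(**{fieldname: m})
            spec = build_model(scaling, kin)
            bal = alternans_balances(spec, cl, protocol)
            rows.append({"model_id": model_id,
                         "condition": f"{tau}_x{m:.2f}",
                         "tau": tau, "multiplier": m,
                         "dapd": bal["dapd"], "srcb_abs": abs(bal["srcb"]),
                         "scb_abs": abs(bal["scb"])})
    return pd.DataFrame(rows)


def kinetics_fit(study: pd.DataFrame) -> dict:
    """R^2 of the linear fits dAPD ~ |SCB| and dAPD ~ |SRCB|."""
    out = {}
    for col in ("scb_abs", "srcb_abs"):
        fit = sps.linregress(study[col].to_numpy(), study["dapd"].to_numpy())
        out[col] = float(fit.rvalue ** 2)
    return out
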