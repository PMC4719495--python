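"""O'Hara–Rudy dynamic (ORd) human ventricular epicardial cell model.

The ORd model describes a single human ventricular myocyte with 41 state
variables: membrane potential, intracellular/subspace Na+, K+ and Ca2+
concentrations, network and junctional sarcoplasmic-reticulum (SR) Ca2+,
Hodgkin–Huxley-type gating variables for the sarcolemmal currents, the
RyR release flux states, and CaMKII activation.  The epicardial variant is
used throughout (the study design considers epicardium only).

Cell-to-cell variability enters as multiplicative factors on eleven maximal
conductances/permeabilities (:class:`ParameterScaling`) and, for the L-type
Ca2+ current kinetics experiments, on three of its time constants
(:class:`KineticsScaling`).

The numerically heavy right-hand side lives in a single numba-compiled
kernel (:func:`_core`) shared by the production Rush–Larsen integrator
(:mod:`cardiopop.engine`) and the plain ODE interface (:func:`derivatives`)
used with SciPy solvers for cross-checks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
from numba import njit

__all__ = [
    "ParameterScaling",
    "KineticsScaling",
    "ModelSpec",
    "build_model",
    "derivatives",
    "initial_state",
    "STATE_NAMES",
    "OBS_NAMES",
    "N_STATE",
    "N_OBS",
]

# ---------------------------------------------------------------------------
# State vector layout
# ---------------------------------------------------------------------------

STATE_NAMES = (
    "v", "nai", "nass", "ki", "kss", "cai", "cass", "cansr", "cajsr",
    "m", "hf", "hs", "j", "hsp", "jp",
    "mL", "hL", "hLp",
    "a", "iF", "iS", "ap", "iFp", "iSp",
    "d", "ff", "fs", "fcaf", "fcas", "jca", "nca", "ffp", "fcafp",
    "xrf", "xrs", "xs1", "xs2", "xk1",
    "Jrelnp", "Jrelp", "CaMKt",
)
N_STATE = len(STATE_NAMES)

# indices 9..39 are relaxation ("gate-like") states updated analytically by
# the Rush-Larsen scheme; everything else is integrated by forward Euler.
GATE_LO, GATE_HI = 9, 40

# auxiliary outputs of the kernel (currents in A/F, fluxes in mM/ms)
OBS_NAMES = (
    "INa", "INaL", "Ito", "ICaL", "ICaNa", "ICaK", "IKr", "IKs", "IK1",
    "INaCa_i", "INaCa_ss", "INaK", "IKb", "INab", "ICab", "IpCa",
    "Jrel", "Jup", "Jleak", "Jtr", "Jdiff", "CaMKa",
    # unbuffered rates of total compartment Ca (for conservative stepping)
    "dcai_raw", "dcass_raw", "dcajsr_raw",
)
N_OBS = len(OBS_NAMES)
OBS = {name: i for i, name in enumerate(OBS_NAMES)}

# ---------------------------------------------------------------------------
# Physical constants and cell geometry (ORd conventions; CGS-ish units:
# ms, mV, mM, A/F).  pi is 3.14 exactly, as in the reference constants.
# ---------------------------------------------------------------------------

R_GAS = 8314.0      # J/kmol/K
TEMP = 310.0        # K
FARADAY = 96485.0   # C/mol

NAO, CAO, KO = 140.0, 1.8, 5.4   # extracellular concentrations (mM)

_PI = 3.14
CELL_L = 0.01       # cm
CELL_RAD = 0.0011   # cm
VCELL = 1000.0 * _PI * CELL_RAD * CELL_RAD * CELL_L   # uL
AGEO = 2.0 * _PI * CELL_RAD * CELL_RAD + 2.0 * _PI * CELL_RAD * CELL_L
ACAP = 2.0 * AGEO   # cm^2
VMYO = 0.68 * VCELL
VNSR = 0.0552 * VCELL
VJSR = 0.0048 * VCELL
VSS = 0.02 * VCELL

# ---------------------------------------------------------------------------
# Parameter scaling containers
# ---------------------------------------------------------------------------

SCALING_NAMES = (
    "s_GNa", "s_GNaL", "s_Gto", "s_GCaL", "s_GKr", "s_GKs", "s_GK1",
    "s_GNaCa", "s_GNaK", "s_PJrel", "s_PJup",
)

KINETICS_NAMES = ("m_tau_d", "m_tau_f", "m_tau_j")

N_PARAM = len(SCALING_NAMES)


@dataclass(frozen=True)
class ParameterScaling:
    """Multiplicative factors on the eleven varied conductances/permeabilities.

    A factor of 1.0 everywhere reproduces the baseline epicardial ORd model;
    the population design varies each factor over [0, 2] (±100%).
    """

    s_GNa: float = 1.0
    s_GNaL: float = 1.0
    s_Gto: float = 1.0
    s_GCaL: float = 1.0
    s_GKr: float = 1.0
    s_GKs: float = 1.0
    s_GK1: float = 1.0
    s_GNaCa: float = 1.0
    s_GNaK: float = 1.0
    s_PJrel: float = 1.0
    s_PJup: float = 1.0

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or not (0.0 <= v <= 2.0):
                raise ValueError(
                    f"{f.name}={v!r} outside the allowed [0, 2] scaling range"
                )

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in SCALING_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "ParameterScaling":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (N_PARAM,):
            raise ValueError(f"expected {N_PARAM} factors, got shape {arr.shape}")
        return cls(**dict(zip(SCALING_NAMES, arr)))


@dataclass(frozen=True)
class KineticsScaling:
    """Multipliers on I_CaL time constants: activation (tau_d), voltage-dependent
    inactivation (tau_f family) and recovery from Ca-dependent inactivation
    (tau_j).  Steady-state curves are untouched.  Allowed range [0.5, 1.5]
    (±50%)."""

    m_tau_d: float = 1.0
    m_tau_f: float = 1.0
    m_tau_j: float = 1.0

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or not (0.5 <= v <= 1.5):
                raise ValueError(
                    f"{f.name}={v!r} outside the allowed [0.5, 1.5] range"
                )

    def as_array(self) -> np.ndarray:
        return np.array([self.m_tau_d, self.m_tau_f, self.m_tau_j], dtype=float)


@dataclass(frozen=True)
class ModelSpec:
    """An evaluatable parameterization: scaling factors packed for the kernel."""

    scaling: ParameterScaling = field(default_factory=ParameterScaling)
    kinetics: KineticsScaling = field(default_factory=KineticsScaling)

    @property
    def p(self) -> np.ndarray:
        """14-vector consumed by the numba kernel."""
        return np.concatenate([self.scaling.as_array(), self.kinetics.as_array()])


def build_model(
    scaling: ParameterScaling | None = None,
    kinetics: KineticsScaling | None = None,
) -> ModelSpec:
    """Build an epicardial ORd variant with the given multiplicative scalings."""
    return ModelSpec(
        scaling=scaling if scaling is not None else ParameterScaling(),
        kinetics=kinetics if kinetics is not None else KineticsScaling(),
    )


# ---------------------------------------------------------------------------
# Initial state
# ---------------------------------------------------------------------------

_Y0 = {
    "v": -87.0, "nai": 7.0, "nass": 7.0, "ki": 145.0, "kss": 145.0,
    "cai": 1.0e-4, "cass": 1.0e-4, "cansr": 1.2, "cajsr": 1.2,
    "m": 0.0, "hf": 1.0, "hs": 1.0, "j": 1.0, "hsp": 1.0, "jp": 1.0,
    "mL": 0.0, "hL": 1.0, "hLp": 1.0,
    "a": 0.0, "iF": 1.0, "iS": 1.0, "ap": 0.0, "iFp": 1.0, "iSp": 1.0,
    "d": 0.0, "ff": 1.0, "fs": 1.0, "fcaf": 1.0, "fcas": 1.0, "jca": 1.0,
    "nca": 0.0, "ffp": 1.0, "fcafp": 1.0,
    "xrf": 0.0, "xrs": 0.0, "xs1": 0.0, "xs2": 0.0, "xk1": 1.0,
    "Jrelnp": 0.0, "Jrelp": 0.0, "CaMKt": 0.0,
}

_STATE_FILE = Path(__file__).with_name("data") / "ord_epi_initial_state.json"


def initial_state(paced: bool = True) -> np.ndarray:
    """Return a baseline epicardial initial state vector.

    paced=True loads the packaged pre-paced steady state (baseline model,
    cycle length 1000 ms); paced=False returns the generic model-definition
    starting values (quiescent-ish, requires pre-beats before analysis).
    """
    if paced and _STATE_FILE.exists():
        data = json.loads(_STATE_FILE.read_text())
        return np.array([data[n] for n in STATE_NAMES], dtype=float)
    return np.array([_Y0[n] for n in STATE_NAMES], dtype=float)


# ---------------------------------------------------------------------------
# The kernel.  One function evaluates, for a given state:
#   * gss/gtau: Rush-Larsen targets and time constants for states 9..39
#   * dy:       forward-Euler derivatives for the non-gate states
#               (dy[0] excludes the stimulus; the integrator adds it)
#   * obs:      currents and fluxes
# ---------------------------------------------------------------------------


@njit(cache=True, fastmath=True)
def _core(y, p, istim, gss, gtau, dy, obs):  # noqa: C901  (monolithic on purpose)
    v = y[0]
    nai = y[1]
    nass = y[2]
    ki = y[3]
    kss = y[4]
    cai = y[5]
    cass = y[6]
    cansr = y[7]
    cajsr = y[8]
    m = y[9]
    hf = y[10]
    hs = y[11]
    jg = y[12]
    hsp = y[13]
    jp = y[14]
    mL = y[15]
    hL = y[16]
    hLp = y[17]
    a = y[18]
    iF = y[19]
    iS = y[20]
    ap = y[21]
    iFp = y[22]
    iSp = y[23]
    d = y[24]
    ff = y[25]
    fs = y[26]
    fcaf = y[27]
    fcas = y[28]
    jca = y[29]
    nca = y[30]
    ffp = y[31]
    fcafp = y[32]
    xrf = y[33]
    xrs = y[34]
    xs1 = y[35]
    xs2 = y[36]
    xk1 = y[37]
    Jrelnp = y[38]
    Jrelp = y[39]
    CaMKt = y[40]

    sGNa = p[0]
    sGNaL = p[1]
    sGto = p[2]
    sGCaL = p[3]
    sGKr = p[4]
    sGKs = p[5]
    sGK1 = p[6]
    sGNaCa = p[7]
    sGNaK = p[8]
    sPJrel = p[9]
    sPJup = p[10]
    mtaud = p[11]
    mtauf = p[12]
    mtauj = p[13]

    # CaMK activation
    KmCaMK = 0.15
    aCaMK = 0.05
    bCaMK = 0.00068
    CaMKo = 0.05
    KmCaM = 0.0015
    CaMKb = CaMKo * (1.0 - CaMKt) / (1.0 + KmCaM / cass)
    CaMKa = CaMKb + CaMKt
    dy[40] = aCaMK * CaMKb * CaMKa - bCaMK * CaMKt
    fphos = 1.0 / (1.0 + KmCaMK / CaMKa)  # CaMK-phosphorylated fraction

    # reversal potentials
    rtf = R_GAS * TEMP / FARADAY
    ENa = rtf * np.log(NAO / nai)
    EK = rtf * np.log(KO / ki)
    EKs = rtf * np.log((KO + 0.01833 * NAO) / (ki + 0.01833 * nai))
    vfrt = v / rtf
    vffrt = v * FARADAY / rtf

    # --- INa (fast sodium) ---
    mss = 1.0 / (1.0 + np.exp(-(v + 39.57) / 9.871))
    tm = 1.0 / (6.765 * np.exp((v + 11.64) / 34.77)
                + 8.552 * np.exp(-(v + 77.42) / 5.955))
    hss = 1.0 / (1.0 + np.exp((v + 82.90) / 6.086))
    thf = 1.0 / (1.432e-5 * np.exp(-(v + 1.196) / 6.285)
                 + 6.149 * np.exp((v + 0.5096) / 20.27))
    ths = 1.0 / (0.009794 * np.exp(-(v + 17.95) / 28.05)
                 + 0.3343 * np.exp((v + 5.730) / 56.66))
    Ahf = 0.99
    Ahs = 1.0 - Ahf
    h = Ahf * hf + Ahs * hs
    jss = hss
    tj = 2.038 + 1.0 / (0.02136 * np.exp(-(v + 100.6) / 8.281)
                        + 0.3052 * np.exp((v + 0.9941) / 38.45))
    hssp = 1.0 / (1.0 + np.exp((v + 89.1) / 6.086))
    thsp = 3.0 * ths
    hp = Ahf * hf + Ahs * hsp
    tjp = 1.46 * tj
    GNa = 75.0 * sGNa
    INa = GNa * (v - ENa) * m ** 3 * ((1.0 - fphos) * h * jg + fphos * hp * jp)

    gss[9] = mss
    gtau[9] = tm
    gss[10] = hss
    gtau[10] = thf
    gss[11] = hss
    gtau[11] = ths
    gss[12] = jss
    gtau[12] = tj
    gss[13] = hssp
    gtau[13] = thsp
    gss[14] = jss
    gtau[14] = tjp

    # --- INaL (late sodium) ---
    mLss = 1.0 / (1.0 + np.exp(-(v + 42.85) / 5.264))
    tmL = tm
    hLss = 1.0 / (1.0 + np.exp((v + 87.61) / 7.488))
    thL = 200.0
    hLssp = 1.0 / (1.0 + np.exp((v + 93.81) / 7.488))
    thLp = 3.0 * thL
    GNaL = 0.0075 * 0.6 * sGNaL  # epicardial
    INaL = GNaL * (v - ENa) * mL * ((1.0 - fphos) * hL + fphos * hLp)

    gss[15] = mLss
    gtau[15] = tmL
    gss[16] = hLss
    gtau[16] = thL
    gss[17] = hLssp
    gtau[17] = thLp

    # --- Ito (transient outward K) ---
    ass = 1.0 / (1.0 + np.exp(-(v - 14.34) / 14.82))
    ta = 1.0515 / (1.0 / (1.2089 * (1.0 + np.exp(-(v - 18.4099) / 29.3814)))
                   + 3.5 / (1.0 + np.exp((v + 100.0) / 29.3814)))
    iss = 1.0 / (1.0 + np.exp((v + 43.94) / 5.711))
    delta_epi = 1.0 - 0.95 / (1.0 + np.exp((v + 70.0) / 5.0))  # epicardial
    tiF = 4.562 + 1.0 / (0.3933 * np.exp(-(v + 100.0) / 100.0)
                         + 0.08004 * np.exp((v + 50.0) / 16.59))
    tiS = 23.62 + 1.0 / (0.001416 * np.exp(-(v + 96.52) / 59.05)
                         + 1.780e-8 * np.exp((v + 114.1) / 8.079))
    tiF *= delta_epi
    tiS *= delta_epi
    AiF = 1.0 / (1.0 + np.exp((v - 213.6) / 151.2))
    AiS = 1.0 - AiF
    i_gate = AiF * iF + AiS * iS
    assp = 1.0 / (1.0 + np.exp(-(v - 24.34) / 14.82))
    dti_develop = 1.354 + 1.0e-4 / (np.exp((v - 167.4) / 15.89)
                                    + np.exp(-(v - 12.23) / 0.2154))
    dti_recover = 1.0 - 0.5 / (1.0 + np.exp((v + 70.0) / 20.0))
    tiFp = dti_develop * dti_recover * tiF
    tiSp = dti_develop * dti_recover * tiS
    ip = AiF * iFp + AiS * iSp
    Gto = 0.02 * 4.0 * sGto  # epicardial
    Ito = Gto * (v - EK) * ((1.0 - fphos) * a * i_gate + fphos * ap * ip)

    gss[18] = ass
    gtau[18] = ta
    gss[19] = iss
    gtau[19] = tiF
    gss[20] = iss
    gtau[20] = tiS
    gss[21] = assp
    gtau[21] = ta
    gss[22] = iss
    gtau[22] = tiFp
    gss[23] = iss
    gtau[23] = tiSp

    # --- ICaL / ICaNa / ICaK (L-type channel) ---
    dss = 1.0 / (1.0 + np.exp(-(v + 3.940) / 4.230))
    td = 0.6 + 1.0 / (np.exp(-0.05 * (v + 6.0)) + np.exp(0.09 * (v + 14.0)))
    td *= mtaud
    fss = 1.0 / (1.0 + np.exp((v + 19.58) / 3.696))
    tff = 7.0 + 1.0 / (0.0045 * np.exp(-(v + 20.0) / 10.0)
                       + 0.0045 * np.exp((v + 20.0) / 10.0))
    tfs = 1000.0 + 1.0 / (0.000035 * np.exp(-(v + 5.0) / 4.0)
                          + 0.000035 * np.exp((v + 5.0) / 6.0))
    tff *= mtauf
    tfs *= mtauf
    Aff = 0.6
    Afs = 1.0 - Aff
    f = Aff * ff + Afs * fs
    fcass = fss
    tfcaf = 7.0 + 1.0 / (0.04 * np.exp(-(v - 4.0) / 7.0)
                         + 0.04 * np.exp((v - 4.0) / 7.0))
    tfcas = 100.0 + 1.0 / (0.00012 * np.exp(-v / 3.0)
                           + 0.00012 * np.exp(v / 7.0))
    Afcaf = 0.3 + 0.6 / (1.0 + np.exp((v - 10.0) / 10.0))
    Afcas = 1.0 - Afcaf
    fca = Afcaf * fcaf + Afcas * fcas
    tjca = 75.0 * mtauj
    tffp = 2.5 * tff
    fp = Aff * ffp + Afs * fs
    tfcafp = 2.5 * tfcaf
    fcap = Afcaf * fcafp + Afcas * fcas
    Kmn = 0.002
    k2n = 1000.0
    km2n = jca * 1.0
    anca = 1.0 / (k2n / km2n + (1.0 + Kmn / cass) ** 4)

    if np.abs(vfrt) < 1.0e-7:
        # v -> 0 limits of the GHK driving terms
        PhiCaL = 2.0 * FARADAY * (cass - 0.341 * CAO)
        PhiCaNa = FARADAY * 0.75 * (nass - NAO)
        PhiCaK = FARADAY * 0.75 * (kss - KO)
    else:
        ex2 = np.exp(2.0 * vfrt)
        ex1 = np.exp(vfrt)
        PhiCaL = 4.0 * vffrt * (cass * ex2 - 0.341 * CAO) / (ex2 - 1.0)
        PhiCaNa = 1.0 * vffrt * (0.75 * nass * ex1 - 0.75 * NAO) / (ex1 - 1.0)
        PhiCaK = 1.0 * vffrt * (0.75 * kss * ex1 - 0.75 * KO) / (ex1 - 1.0)

    PCa = 0.0001 * 1.2 * sGCaL  # epicardial
    PCap = 1.1 * PCa
    PCaNa = 0.00125 * PCa
    PCaK = 3.574e-4 * PCa
    PCaNap = 0.00125 * PCap
    PCaKp = 3.574e-4 * PCap
    ICaL = (1.0 - fphos) * PCa * PhiCaL * d * (f * (1.0 - nca) + jca * fca * nca) \
        + fphos * PCap * PhiCaL * d * (fp * (1.0 - nca) + jca * fcap * nca)
    ICaNa = (1.0 - fphos) * PCaNa * PhiCaNa * d * (f * (1.0 - nca) + jca * fca * nca) \
        + fphos * PCaNap * PhiCaNa * d * (fp * (1.0 - nca) + jca * fcap * nca)
    ICaK = (1.0 - fphos) * PCaK * PhiCaK * d * (f * (1.0 - nca) + jca * fca * nca) \
        + fphos * PCaKp * PhiCaK * d * (fp * (1.0 - nca) + jca * fcap * nca)

    gss[24] = dss
    gtau[24] = td
    gss[25] = fss
    gtau[25] = tff
    gss[26] = fss
    gtau[26] = tfs
    gss[27] = fcass
    gtau[27] = tfcaf
    gss[28] = fcass
    gtau[28] = tfcas
    gss[29] = fcass
    gtau[29] = tjca
    gss[30] = anca * k2n / km2n
    gtau[30] = 1.0 / km2n
    gss[31] = fss
    gtau[31] = tffp
    gss[32] = fcass
    gtau[32] = tfcafp

    # --- IKr ---
    xrss = 1.0 / (1.0 + np.exp(-(v + 8.337) / 6.789))
    txrf = 12.98 + 1.0 / (0.3652 * np.exp((v - 31.66) / 3.869)
                          + 4.123e-5 * np.exp(-(v - 47.78) / 20.38))
    txrs = 1.865 + 1.0 / (0.06629 * np.exp((v - 34.70) / 7.355)
                          + 1.128e-5 * np.exp(-(v - 29.74) / 25.94))
    Axrf = 1.0 / (1.0 + np.exp((v + 54.81) / 38.21))
    Axrs = 1.0 - Axrf
    xr = Axrf * xrf + Axrs * xrs
    rkr = (1.0 / (1.0 + np.exp((v + 55.0) / 75.0))) \
        * (1.0 / (1.0 + np.exp((v - 10.0) / 30.0)))
    GKr = 0.046 * 1.3 * sGKr  # epicardial
    IKr = GKr * np.sqrt(KO / 5.4) * xr * rkr * (v - EK)

    gss[33] = xrss
    gtau[33] = txrf
    gss[34] = xrss
    gtau[34] = txrs

    # --- IKs ---
    xs1ss = 1.0 / (1.0 + np.exp(-(v + 11.60) / 8.932))
    txs1 = 817.3 + 1.0 / (2.326e-4 * np.exp((v + 48.28) / 17.80)
                          + 0.001292 * np.exp(-(v + 210.0) / 230.0))
    xs2ss = xs1ss
    txs2 = 1.0 / (0.01 * np.exp((v - 50.0) / 20.0)
                  + 0.0193 * np.exp(-(v + 66.54) / 31.0))
    KsCa = 1.0 + 0.6 / (1.0 + (3.8e-5 / cai) ** 1.4)
    GKs = 0.0034 * 1.4 * sGKs  # epicardial
    IKs = GKs * KsCa * xs1 * xs2 * (v - EKs)

    gss[35] = xs1ss
    gtau[35] = txs1
    gss[36] = xs2ss
    gtau[36] = txs2

    # --- IK1 ---
    xk1ss = 1.0 / (1.0 + np.exp(-(v + 2.5538 * KO + 144.59)
                                / (1.5692 * KO + 3.8115)))
    txk1 = 122.2 / (np.exp(-(v + 127.2) / 20.36) + np.exp((v + 236.8) / 69.33))
    rk1 = 1.0 / (1.0 + np.exp((v + 105.8 - 2.6 * KO) / 9.493))
    GK1 = 0.1908 * 1.2 * sGK1  # epicardial
    IK1 = GK1 * np.sqrt(KO) * rk1 * xk1 * (v - EK)

    gss[37] = xk1ss
    gtau[37] = txk1

    # --- INaCa (Na/Ca exchanger, bulk and subspace components) ---
    kna1 = 15.0
    kna2 = 5.0
    kna3 = 88.12
    kasymm = 12.5
    wna = 6.0e4
    wca = 6.0e4
    wnaca = 5.0e3
    kcaon = 1.5e6
    kcaoff = 5.0e3
    qna = 0.5224
    qca = 0.1670
    hca = np.exp(qca * vfrt)
    hna = np.exp(qna * vfrt)
    Gncx = 0.0008 * 1.1 * sGNaCa  # epicardial
    KmCaAct = 150.0e-6
    zca = 2.0
    zna = 1.0

    # bulk (cai, nai)
    h1 = 1.0 + nai / kna3 * (1.0 + hna)
    h2 = nai * hna / (kna3 * h1)
    h3 = 1.0 / h1
    h4 = 1.0 + nai / kna1 * (1.0 + nai / kna2)
    h5 = nai * nai / (h4 * kna1 * kna2)
    h6 = 1.0 / h4
    h7 = 1.0 + NAO / kna3 * (1.0 + 1.0 / hna)
    h8 = NAO / (kna3 * hna * h7)
    h9 = 1.0 / h7
    h10 = kasymm + 1.0 + NAO / kna1 * (1.0 + NAO / kna2)
    h11 = NAO * NAO / (h10 * kna1 * kna2)
    h12 = 1.0 / h10
    k1 = h12 * CAO * kcaon
    k2 = kcaoff
    k3p = h9 * wca
    k3pp = h8 * wnaca
    k3 = k3p + k3pp
    k4p = h3 * wca / hca
    k4pp = h2 * wnaca
    k4 = k4p + k4pp
    k5 = kcaoff
    k6 = h6 * cai * kcaon
    k7 = h5 * h2 * wna
    k8 = h8 * h11 * wna
    x1 = k2 * k4 * (k7 + k6) + k5 * k7 * (k2 + k3)
    x2 = k1 * k7 * (k4 + k5) + k4 * k6 * (k1 + k8)
    x3 = k1 * k3 * (k7 + k6) + k8 * k6 * (k2 + k3)
    x4 = k2 * k8 * (k4 + k5) + k3 * k5 * (k1 + k8)
    E1 = x1 / (x1 + x2 + x3 + x4)
    E2 = x2 / (x1 + x2 + x3 + x4)
    E3 = x3 / (x1 + x2 + x3 + x4)
    E4 = x4 / (x1 + x2 + x3 + x4)
    allo = 1.0 / (1.0 + (KmCaAct / cai) ** 2)
    JncxNa = 3.0 * (E4 * k7 - E1 * k8) + E3 * k4pp - E2 * k3pp
    JncxCa = E2 * k2 - E1 * k1
    INaCa_i = 0.8 * Gncx * allo * (zna * JncxNa + zca * JncxCa)

    # subspace (cass, nass)
    h1 = 1.0 + nass / kna3 * (1.0 + hna)
    h2 = nass * hna / (kna3 * h1)
    h3 = 1.0 / h1
    h4 = 1.0 + nass / kna1 * (1.0 + nass / kna2)
    h5 = nass * nass / (h4 * kna1 * kna2)
    h6 = 1.0 / h4
    k4p = h3 * wca / hca
    k4pp = h2 * wnaca
    k4 = k4p + k4pp
    k6 = h6 * cass * kcaon
    k7 = h5 * h2 * wna
    x1 = k2 * k4 * (k7 + k6) + k5 * k7 * (k2 + k3)
    x2 = k1 * k7 * (k4 + k5) + k4 * k6 * (k1 + k8)
    x3 = k1 * k3 * (k7 + k6) + k8 * k6 * (k2 + k3)
    x4 = k2 * k8 * (k4 + k5) + k3 * k5 * (k1 + k8)
    E1 = x1 / (x1 + x2 + x3 + x4)
    E2 = x2 / (x1 + x2 + x3 + x4)
    E3 = x3 / (x1 + x2 + x3 + x4)
    E4 = x4 / (x1 + x2 + x3 + x4)
    allo = 1.0 / (1.0 + (KmCaAct / cass) ** 2)
    JncxNa = 3.0 * (E4 * k7 - E1 * k8) + E3 * k4pp - E2 * k3pp
    JncxCa = E2 * k2 - E1 * k1
    INaCa_ss = 0.2 * Gncx * allo * (zna * JncxNa + zca * JncxCa)

    # --- INaK (Na/K pump) ---
    k1p = 949.5
    k1m = 182.4
    k2p = 687.2
    k2m = 39.4
    k3pk = 1899.0
    k3m = 79300.0
    k4pk = 639.0
    k4m = 40.0
    Knai0 = 9.073
    Knao0 = 27.78
    delta = -0.1550
    Knai = Knai0 * np.exp(delta * vfrt / 3.0)
    Knao = Knao0 * np.exp((1.0 - delta) * vfrt / 3.0)
    Kki = 0.5
    Kko = 0.3582
    MgADP = 0.05
    MgATP = 9.8
    Kmgatp = 1.698e-7
    H = 1.0e-7
    eP = 4.2
    Khp = 1.698e-7
    Knap = 224.0
    Kxkur = 292.0
    P = eP / (1.0 + H / Khp + nai / Knap + ki / Kxkur)
    a1 = (k1p * (nai / Knai) ** 3) \
        / ((1.0 + nai / Knai) ** 3 + (1.0 + ki / Kki) ** 2 - 1.0)
    b1 = k1m * MgADP
    a2 = k2p
    b2 = (k2m * (NAO / Knao) ** 3) \
        / ((1.0 + NAO / Knao) ** 3 + (1.0 + KO / Kko) ** 2 - 1.0)
    a3 = (k3pk * (KO / Kko) ** 2) \
        / ((1.0 + NAO / Knao) ** 3 + (1.0 + KO / Kko) ** 2 - 1.0)
    b3 = (k3m * P * H) / (1.0 + MgATP / Kmgatp)
    a4 = (k4pk * MgATP / Kmgatp) / (1.0 + MgATP / Kmgatp)
    b4 = (k4m * (ki / Kki) ** 2) \
        / ((1.0 + nai / Knai) ** 3 + (1.0 + ki / Kki) ** 2 - 1.0)
    x1 = a4 * a1 * a2 + b2 * b4 * b3 + a2 * b4 * b3 + b3 * a1 * a2
    x2 = b2 * b1 * b4 + a1 * a2 * a3 + a3 * b1 * b4 + a2 * a3 * b4
    x3 = a2 * a3 * a4 + b3 * b2 * b1 + b2 * b1 * a4 + a3 * a4 * b1
    x4 = b4 * b3 * b2 + a3 * a4 * a1 + b2 * a4 * a1 + b3 * b2 * a1
    E1 = x1 / (x1 + x2 + x3 + x4)
    E2 = x2 / (x1 + x2 + x3 + x4)
    E3 = x3 / (x1 + x2 + x3 + x4)
    E4 = x4 / (x1 + x2 + x3 + x4)
    zk = 1.0
    JnakNa = 3.0 * (E1 * a3 - E2 * b3)
    JnakK = 2.0 * (E4 * b1 - E3 * a1)
    Pnak = 30.0 * 0.9 * sGNaK  # epicardial
    INaK = Pnak * (zna * JnakNa + zk * JnakK)

    # --- background and pump currents ---
    xkb = 1.0 / (1.0 + np.exp(-(v - 14.48) / 18.34))
    GKb = 0.003 * 0.6  # epicardial
    IKb = GKb * xkb * (v - EK)
    if np.abs(vfrt) < 1.0e-7:
        INab = 3.75e-10 * FARADAY * (nai - NAO)
        ICab = 2.5e-8 * 2.0 * FARADAY * (cai - 0.341 * CAO)  # v->0 limits
    else:
        ex1 = np.exp(vfrt)
        ex2 = np.exp(2.0 * vfrt)
        INab = 3.75e-10 * vffrt * (nai * ex1 - NAO) / (ex1 - 1.0)
        ICab = 2.5e-8 * 4.0 * vffrt * (cai * ex2 - 0.341 * CAO) / (ex2 - 1.0)
    IpCa = 0.0005 * cai / (0.0005 + cai)

    # --- SR fluxes ---
    # RyR release (CaMK-split), driven by ICaL with JSR-load dependence
    bt = 4.75
    a_rel = 0.5 * bt
    Jrel_inf = a_rel * (-ICaL) / (1.0 + (1.5 / cajsr) ** 8)
    tau_rel = bt / (1.0 + 0.0123 / cajsr)
    if tau_rel < 0.001:
        tau_rel = 0.001
    btp = 1.25 * bt
    a_relp = 0.5 * btp
    Jrel_infp = a_relp * (-ICaL) / (1.0 + (1.5 / cajsr) ** 8)
    tau_relp = btp / (1.0 + 0.0123 / cajsr)
    if tau_relp < 0.001:
        tau_relp = 0.001
    gss[38] = Jrel_inf
    gtau[38] = tau_rel
    gss[39] = Jrel_infp
    gtau[39] = tau_relp
    Jrel = sPJrel * ((1.0 - fphos) * Jrelnp + fphos * Jrelp)

    # SERCA uptake (epicardial x1.3) and NSR leak
    Jupnp = 1.3 * 0.004375 * cai / (cai + 0.00092)
    Jupp = 1.3 * 2.75 * 0.004375 * cai / (cai + 0.00092 - 0.00017)
    Jleak = 0.0039375 * cansr / 15.0
    Jup = sPJup * ((1.0 - fphos) * Jupnp + fphos * Jupp) - Jleak
    Jtr = (cansr - cajsr) / 100.0

    # --- ionic diffusion between subspace and bulk ---
    JdiffNa = (nass - nai) / 2.0
    JdiffK = (kss - ki) / 2.0
    Jdiff = (cass - cai) / 0.2

    # --- concentration derivatives ---
    acf = ACAP / FARADAY
    dy[1] = -(INa + INaL + 3.0 * INaCa_i + 3.0 * INaK + INab) * acf / VMYO \
        + JdiffNa * VSS / VMYO
    dy[2] = -(ICaNa + 3.0 * INaCa_ss) * acf / VSS - JdiffNa
    dy[3] = -(Ito + IKr + IKs + IK1 + IKb + istim - 2.0 * INaK) * acf / VMYO \
        + JdiffK * VSS / VMYO
    dy[4] = -ICaK * acf / VSS - JdiffK

    cmdnmax = 0.05 * 1.3  # epicardial
    kmcmdn = 0.00238
    trpnmax = 0.07
    kmtrpn = 0.0005
    BSRmax = 0.047
    KmBSR = 0.00087
    BSLmax = 1.124
    KmBSL = 0.0087
    csqnmax = 10.0
    kmcsqn = 0.8

    raw_cai = (-(IpCa + ICab - 2.0 * INaCa_i) * acf / (2.0 * VMYO)
               - Jup * VNSR / VMYO + Jdiff * VSS / VMYO)
    Bcai = 1.0 / (1.0 + cmdnmax * kmcmdn / (kmcmdn + cai) ** 2
                  + trpnmax * kmtrpn / (kmtrpn + cai) ** 2)
    dy[5] = Bcai * raw_cai
    raw_cass = (-(ICaL - 2.0 * INaCa_ss) * acf / (2.0 * VSS)
                + Jrel * VJSR / VSS - Jdiff)
    Bcass = 1.0 / (1.0 + BSRmax * KmBSR / (KmBSR + cass) ** 2
                   + BSLmax * KmBSL / (KmBSL + cass) ** 2)
    dy[6] = Bcass * raw_cass
    dy[7] = Jup - Jtr * VJSR / VNSR
    raw_cajsr = Jtr - Jrel
    Bcajsr = 1.0 / (1.0 + csqnmax * kmcsqn / (kmcsqn + cajsr) ** 2)
    dy[8] = Bcajsr * raw_cajsr

    # membrane potential (stimulus added here so dy[0] is the full dv/dt)
    dy[0] = -(INa + INaL + Ito + ICaL + ICaNa + ICaK + IKr + IKs + IK1
              + INaCa_i + INaCa_ss + INaK + INab + IKb + IpCa + ICab + istim)

    obs[0] = INa
    obs[1] = INaL
    obs[2] = Ito
    obs[3] = ICaL
    obs[4] = ICaNa
    obs[5] = ICaK
    obs[6] = IKr
    obs[7] = IKs
    obs[8] = IK1
    obs[9] = INaCa_i
    obs[10] = INaCa_ss
    obs[11] = INaK
    obs[12] = IKb
    obs[13] = INab
    obs[14] = ICab
    obs[15] = IpCa
    obs[16] = Jrel
    obs[17] = Jup
    obs[18] = Jleak
    obs[19] = Jtr
    obs[20] = Jdiff
    obs[21] = CaMKa
    obs[22] = raw_cai
    obs[23] = raw_cass
    obs[24] = raw_cajsr


@njit(cache=True)
def _rhs(y, p, istim, dy, gss, gtau, obs):
    """Full derivative vector (gates converted from (ss, tau) form)."""
    _core(y, p, istim, gss, gtau, dy, obs)
    for k in range(GATE_LO, GATE_HI):
        dy[k] = (gss[k] - y[k]) / gtau[k]


def derivatives(t, y, spec: ModelSpec, i_stim: float = 0.0) -> np.ndarray:
    """Time derivative of the full state vector (for SciPy solvers).

    ``i_stim`` is the applied stimulus current in A/F (negative =
    depolarizing, ORd convention).  Raises ``FloatingPointError`` with a
    state dump if the derivative is non-finite.
    """
    y = np.asarray(y, dtype=float)
    dy = np.empty(N_STATE)
    gss = np.empty(N_STATE)
    gtau = np.empty(N_STATE)
    obs = np.empty(N_OBS)
    _rhs(y, spec.p, float(i_stim), dy, gss, gtau, obs)
    if not np.all(np.isfinite(dy)):
        bad = [STATE_NAMES[k] for k in range(N_STATE) if not np.isfinite(dy[k])]
        raise FloatingPointError(
            f"non-finite derivative for {bad} at t={t}; state={dict(zip(STATE_NAMES, y))}"
        )
    return dy


def evaluate_currents(y, spec: ModelSpec, i_stim: float = 0.0) -> dict:
    """Currents (A/F) and SR fluxes (mM/ms) at a given state."""
    y = np.asarray(y, dtype=float)
    dy = np.empty(N_STATE)
    gss = np.empty(N_STATE)
    gtau = np.empty(N_STATE)
    obs = np.empty(N_OBS)
    _rhs(y, spec.p, float(i_stim), dy, gss, gtau, obs)
    return dict(zip(OBS_NAMES, obs))


# total Ca in each compartment including instantaneous buffers (mM of the
# compartment volume); used by conservation checks and the balance module
def total_calcium(y) -> float:
    """Total cell Ca content, volume-weighted to mmol per litre cytosol."""
    y = np.asarray(y, dtype=float)
    cai, cass, cansr, cajsr = y[5], y[6], y[7], y[8]
    cmdnmax = 0.05 * 1.3
    kmcmdn = 0.00238
    trpnmax = 0.07
    kmtrpn = 0.0005
    BSRmax = 0.047
    KmBSR = 0.00087
    BSLmax = 1.124
    KmBSL = 0.0087
    csqnmax = 10.0
    kmcsqn = 0.8
    cyt = cai + cmdnmax * cai / (kmcmdn + cai) + trpnmax * cai / (kmtrpn + cai)
    ss = cass + BSRmax * cass / (KmBSR + cass) + BSLmax * cass / (KmBSL + cass)
    jsr = cajsr + csqnmax * cajsr / (kmcsqn + cajsr)
    tot = cyt * VMYO + ss * VSS + cansr * VNSR + jsr * VJSR
    return tot / VMYO
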