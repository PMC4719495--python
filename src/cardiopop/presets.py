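"""Representative parameter sets from Latin-Hypercube screens.

These scaling vectors were identified by seeded LHS screens of the
calibrated population run with this package and are frozen here as
reproducible, named examples: Fork-type and Eye-type alternans models of
various magnitudes, a CaT-only alternans model, and the longest/shortest-
APD accepted normal models (the reference set used by the kinetics study).
They are ordinary points of the [0, 2]^11 sampling space, provided so that
mechanism-level analyses (clamp experiments, balance bookkeeping,
interventions) do not require re-discovering alternans models by large
population runs.
"""

from __future__ import annotations

from .ord import ParameterScaling

__all__ = [
    "ALTERNANS_PRESETS",
    "NORMAL_REFERENCES",
    "SCREEN_ALTERNANS",
    "alternans_presets",
    "normal_references",
    "screen_alternans",
]

# order: GNa, GNaL, Gto, GCaL, GKr, GKs, GK1, GNaCa, GNaK, PJrel, PJup
_VECTORS = {
    # open (Fork-type) restitution bifurcations
    "fork_large": (0.2744, 1.2168, 1.9629, 1.1777, 1.6260, 1.2498, 0.0610,
                   0.8515, 0.8058, 0.8760, 0.2684),     # dAPD up to ~47 ms
    "fork_moderate": (0.3332, 0.7338, 1.5641, 1.5404, 1.3333, 1.7922, 0.1946,
                      1.8434, 1.7780, 1.3026, 0.3829),
    "fork_early_onset": (0.7878, 1.2814, 0.2995, 1.6289, 1.3769, 0.0409,
                         1.9315, 0.5454, 0.5966, 1.9124, 0.2439),  # onset 550
    "fork_mild": (0.4727, 0.9742, 0.0978, 0.9314, 1.4024, 0.0930, 0.6900,
                  0.8659, 0.6931, 0.4686, 0.4059),
    # calcium alternans without significant APD alternans
    "cat_only": (0.2847, 0.9868, 0.9690, 1.9442, 1.9762, 1.5957, 0.5856,
                 1.8652, 1.4436, 1.8698, 0.7113),
    # closed (Eye-type) bifurcations: strong G_CaL and G_NaCa, weak SERCA
    "eye_large": (0.3476, 1.3220, 1.7120, 1.6902, 1.1521, 1.5563, 1.4145,
                  1.9210, 1.7720, 1.3914, 0.5533),    # dAPD up to ~13 ms
    "eye_moderate": (0.5928, 1.1016, 1.9733, 1.3504, 1.4166, 1.0596, 1.0199,
                     1.8439, 1.1239, 1.6849, 0.5868),
    "eye_mid_onset": (0.2492, 1.7982, 1.0302, 1.7109, 1.7115, 0.0486, 0.3892,
                      1.7285, 1.6520, 1.9443, 0.5933),
    "eye_long_onset": (0.4050, 1.2016, 1.1408, 1.4165, 1.1446, 0.5508,
                       1.5810, 1.7370, 0.3237, 1.9822, 0.3997),  # onset 550
}

_NORMAL_VECTORS = {
    "normal_long_apd": (1.5838, 0.5265, 1.2030, 1.7134, 1.0096, 0.1412,
                        0.1172, 0.2284, 1.6226, 0.8123, 0.8091),
    "normal_short_apd": (1.4320, 1.8639, 1.9519, 0.4603, 1.7659, 0.1142,
                         1.0156, 1.0571, 1.4482, 0.1748, 0.9707),
    "baseline": (1.0,) * 11,
}

# The complete alternans yield (no curation) of a 500-model LHS screen of
# the calibrated population (LHS seed 2024, synthetic-envelope seed 2024,
# 200 pre-beats/CL): a population-representative alternans sample for
# balance-correlation and intervention analyses at desk scale.
_SCREEN_ALTERNANS = (
    ("screen_63", "fork", (0.3332, 0.7338, 1.5641, 1.5404, 1.3333, 1.7922, 0.1946, 1.8434, 1.7780, 1.3026, 0.3829)),
    ("screen_74", "fork", (0.2995, 1.2125, 0.2723, 0.4951, 0.7077, 1.1499, 0.3802, 0.9878, 1.1782, 1.6034, 0.8211)),
    ("screen_161", "fork", (0.6532, 0.3394, 0.7951, 1.5084, 1.3540, 1.6982, 0.6636, 0.7002, 0.3718, 0.3429, 0.2787)),
    ("screen_197", "fork", (0.7878, 1.2814, 0.2995, 1.6289, 1.3769, 0.0409, 1.9315, 0.5454, 0.5966, 1.9124, 0.2439)),
    ("screen_241", "fork", (0.4727, 0.9742, 0.0978, 0.9314, 1.4024, 0.0930, 0.6900, 0.8659, 0.6931, 0.4686, 0.4059)),
    ("screen_294", "cat_only", (0.2847, 0.9868, 0.9690, 1.9442, 1.9762, 1.5957, 0.5856, 1.8652, 1.4436, 1.8698, 0.7113)),
    ("screen_297", "fork", (0.6293, 1.0729, 1.8341, 1.4116, 1.8336, 1.4953, 1.6015, 1.9134, 1.7535, 1.5662, 0.5585)),
    ("screen_304", "fork", (1.5127, 0.1557, 1.1957, 1.3447, 1.6161, 0.0195, 0.2236, 0.8894, 0.0579, 0.9325, 0.2487)),
    ("screen_325", "fork", (0.2744, 1.2168, 1.9629, 1.1777, 1.6260, 1.2498, 0.0610, 0.8515, 0.8058, 0.8760, 0.2684)),
    ("screen_363", "fork", (1.0716, 1.1305, 1.9026, 1.7200, 1.5057, 1.3398, 1.8887, 1.7114, 0.6574, 1.7752, 0.3746)),
    ("screen_422", "fork", (0.4220, 1.2018, 1.0976, 0.7551, 1.0405, 1.9548, 1.6619, 1.6549, 1.9509, 1.7232, 0.7793)),
)

SCREEN_ALTERNANS = [(name, label, ParameterScaling(*vec))
                    for name, label, vec in _SCREEN_ALTERNANS]

ALTERNANS_PRESETS = {name: ParameterScaling(*vec)
                     for name, vec in _VECTORS.items()}
NORMAL_REFERENCES = {name: ParameterScaling(*vec)
                     for name, vec in _NORMAL_VECTORS.items()}


def alternans_presets() -> dict:
    """Named alternans-prone parameter sets (Fork/Eye/CaT-only)."""
    return dict(ALTERNANS_PRESETS)


def normal_references() -> dict:
    """Baseline plus longest/shortest-APD accepted normal models."""
    return dict(NORMAL_REFERENCES)


def screen_alternans() -> list:
    """(name, screen label, ParameterScaling) for the full screen yield."""
    return list(SCREEN_ALTERNANS)
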