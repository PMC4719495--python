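# cardiopop

Population-of-models analysis of repolarization alternans in human
ventricular cardiomyocytes.

## The problem

Repolarization alternans — stable beat-to-beat (period-2) oscillation of
action potential duration (APD) — is an established arrhythmia risk marker.
In human epicardial recordings two distinct restitution patterns appear as
pacing accelerates: **Eye-type** alternans (a *closed* bifurcation: APD
alternans appear at intermediate rates and vanish again at the fastest
rates) and **Fork-type** alternans (an *open* bifurcation: alternans persist
at the fastest rates).  `cardiopop` reproduces the in-silico half of that
study for researchers in cardiac electrophysiology: it builds a calibrated
population of biophysically detailed human ventricular cell models, finds
and classifies the alternans phenotypes, traces them to sarcoplasmic-
reticulum (SR) calcium-cycling fluctuations, and runs the pharmacological
interventions that suppress them.

## The model and statistics at its core

* **Cell model** — the O'Hara–Rudy dynamic (ORd) human ventricular
  epicardial model (41 states), with multiplicative scaling factors on the
  11 key conductances/permeabilities (G_Na, G_NaL, G_to, G_CaL, G_Kr, G_Ks,
  G_K1, G_NaCa, G_NaK, P_Jrel, P_Jup), each sampled over ±100% by Latin
  Hypercube Sampling, and optional ±50% scaling of the I_CaL time constants
  τ_d, τ_f, τ_j.
* **Calibration** — per-CL min/max envelopes on steady-state APD at six
  pacing cycle lengths (600→350 ms), derived from activation-recovery-
  interval (ARI) data; a synthetic hierarchical ARI generator stands in for
  unavailable patient recordings.
* **Alternans metrics** — ΔAPD = mean |APD(n) − APD(n+1)| (threshold 5 ms),
  ΔCaT for the calcium transient; classification into normal / Eye / Fork /
  CaT-only with the alternans-onset CL.
* **Calcium balances** — per beat, in µmol per litre cytosol:
  SRCB = ∫(J_up − J_rel) dt (volume-weighted; net SR Ca gain) and
  SCB = ∫(2 I_NaCa − I_CaL − I_Cab − I_pCa) dt · A_cap/(2F V_myo)
  (net sarcolemmal Ca gain).  Both vanish at a period-1 steady state and
  oscillate in sign during alternans; their magnitudes track ΔAPD.
* **Statistics** — Pearson and partial correlation (biomarkers vs
  parameters), Mann–Whitney U (exact for small samples) for
  normal-vs-alternans comparisons.
* **Interventions** — I_NaCa block (20/40/60%) on alternans models and
  one-at-a-time I_CaL kinetics variation.

## Worked example

Pace the baseline epicardial model to steady state and measure it:

```python
from cardiopop import build_model, initial_state, ParameterScaling
from cardiopop.protocols import pace, PacingProtocol, run_restitution
from cardiopop.biomarkers import beat_biomarkers
from cardiopop.balance import srcb_per_beat, scb_per_beat

spec = build_model()                      # all scale factors = 1.0
series = pace(spec, cl=1000.0, n_prebeats=300, n_record=2,
              initial_state=initial_state())
b = beat_biomarkers(series[0])
print(f"APD90  {b.APD:6.1f} ms")
print(f"RMP    {b.RMP:6.1f} mV   Vmax {b.Vmax:5.1f} mV")
print(f"CaT    {b.CaTamp*1e3:6.3f} uM amplitude")
print(f"SRCB   {srcb_per_beat(series[0]):+8.4f} umol/L per beat")
print(f"SCB    {scb_per_beat(series[0]):+8.4f} umol/L per beat")
```

prints (this implementation, CL 1000 ms):

```
APD90   228.5 ms
RMP     -87.9 mV   Vmax  35.5 mV
CaT     0.609 uM amplitude
SRCB    +0.0011 umol/L per beat
SCB     +0.0013 umol/L per beat
```

i.e. a normal epicardial action potential (APD90 ≈ 229 ms), and calcium
balances that close to ~0.03% of the per-beat Ca turnover at steady state —
the conservation property the alternans analysis rests on.  An alternans
model (e.g. from `cardiopop.presets`) run through `run_restitution` shows a
period-2 APD sequence at intermediate CLs, with SRCB/SCB of alternating
sign on consecutive beats.

A full scaled-down study from the command line:

```bash
cardiopop run-all --n-models 200 --seed 1 --prebeats 150 --out study_out
```

writes `population.csv`, `classification.csv`, `balance.csv`,
`partial_correlation.csv`, `group_comparison.csv`, the intervention tables
and a run manifest into `study_out/`.

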