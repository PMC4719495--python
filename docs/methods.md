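# Methods

## The cell model

`cardiopop` is built on a transcription of the O'Hara–Rudy dynamic (ORd)
model of the human ventricular myocyte, in its epicardial variant (41 state
variables: membrane potential; intracellular, subspace and SR Na⁺/K⁺/Ca²⁺
concentrations; Hodgkin–Huxley gating variables; RyR release-flux states;
CaMKII activation).  The epicardial parameter set is used throughout
because the study design concerns epicardial recordings and models only.

Cell-to-cell variability is represented by eleven multiplicative factors on
maximal conductances and permeabilities — G_Na, G_NaL, G_to, G_CaL (the
L-type Ca²⁺ permeability P_Ca), G_Kr, G_Ks, G_K1, G_NaCa (exchanger
conductance), G_NaK (pump activity), P_Jrel (RyR release permeability) and
P_Jup (SERCA uptake permeability) — each varied over [0, 2], i.e. ±100% of
the published value.  A factor of 1.0 everywhere reproduces the baseline
model.  For the L-type-current kinetics experiments, three time constants
can additionally be scaled by ±50%: activation (τ_d), voltage-dependent
inactivation (the τ_f family: τ_ff, τ_fs and the CaMK variants), and
recovery from Ca-dependent inactivation (τ_j, the `jca` gate).  Kinetics
scaling multiplies the voltage-dependent time-constant expressions
pointwise and leaves all steady-state curves unchanged.

Because no independent ORd implementation is importable in this
environment, the transcription is validated internally rather than against
an external oracle: (i) charge bookkeeping (dV/dt ≡ −ΣI) and whole-cell
calcium conservation (below) hold to high precision; (ii) the quiescent
model sits at an equilibrium; (iii) directional sensitivities reproduce the
expected physiology (G_Na removal abolishes the upstroke, G_CaL prolongs
APD, G_Kr shortens it, RMP is most sensitive to G_K1); (iv) the baseline
epicardial APD90 at CL 1000 ms (228.5 ms) and CaT amplitude (0.61 µM) fall
in the published epicardial range.  Quantitative values frozen in the test
suite are regression values computed by this implementation.

One deliberate finding: halving G_K1 *hyperpolarizes* diastolic Vm slightly
in this model (reduced K⁺ efflux raises [K]i and shifts E_K downward),
although RMP remains most sensitive to G_K1 of all sampled conductances.
Tests assert the sensitivity ranking, not a sign that the model does not
produce.

## Numerical integration

The production integrator is a hybrid Rush–Larsen / forward-Euler scheme
compiled with numba:

* the 31 relaxation states (gates, the L-type mode switch `nca`, the RyR
  flux states) use the exact exponential update
  `g ← g_ss + (g − g_ss)·exp(−Δt/τ)` (unconditionally stable);
* membrane potential, unbuffered concentrations and CaMKII use forward
  Euler;
* the three instantaneously buffered Ca compartments (cytosol: calmodulin +
  troponin; subspace: BSR + BSL; JSR: calsequestrin) use a *conservative*
  formulation: the conserved total (free + bound) Ca is advanced by the
  unbuffered flux rate and the free concentration recovered by a two-step
  Newton inversion of the buffer relation.  A naive Euler step on the
  buffered ODE form loses ~0.15 µmol Ca per litre cytosol per beat through
  buffer-curvature linearization — large enough to swamp the calcium-balance
  analysis this package exists for; the conservative step closes whole-cell
  Ca conservation to ~10⁻⁶ relative.

Step sizes follow a three-phase schedule within each beat: 0.005 ms during
the stimulus/upstroke (first 5 ms), 0.02 ms through plateau and calcium
transient (to 300 ms), 0.05 ms in diastole; unrecorded pre-beats use a
coarser schedule (0.025/0.1 ms).  Every phase step divides the 0.5 ms
output sampling interval, so samples land on an exact grid.  The schedule
was fixed by convergence testing — halving every step changes APD90 by
< 0.05 ms and per-beat balances by well under 0.5% — and a test cross-checks
APD90 against an LSODA (SciPy) solve of the same right-hand side at
rtol 10⁻⁸.  The stimulus is rectangular, −80 A/F for 0.5 ms (the ORd
convention; no published value exists for this protocol).

Per-beat flux integrals (I_CaL, I_NaCa components, background/pump Ca
currents, J_rel, J_up) are accumulated *inside* the stepper at sub-step
resolution with the same left-endpoint quadrature as the state update, so
balance quantities are exactly consistent with the integrated dynamics;
re-integrating the 0.5 ms-sampled traces by trapezoid misses the upstroke
current spike by a few percent and is used only for externally supplied
traces.

## Protocols

Dynamic (steady-state) restitution paces a descending CL ladder —
600…350 ms in 50 ms steps by default, optionally extended to 200 ms — with
state carry-over from one CL to the next, mimicking an in vivo step
protocol.  Diastolic interval is CL − APD90 of the preceding beat.  Capture
requires peak Vm > 0 mV within 50 ms of the stimulus; the fastest *captured*
CL defines Fork-type status so 2:1 block cannot masquerade as alternans
disappearance.

Beat counts.  The config default is 500 pre-beats per CL (with carry-over)
and 4 recorded beats.  Absolute APD converges slowly in ORd — intracellular
Na⁺ adaptation has a several-hundred-beat time constant, so APD at 150
pre-beats still carries a few ms of drift, and the doubling-invariance test
(< 1 ms change when pre-beats double) is asserted at 800 pre-beats.
Beat-to-beat *differences* (ΔAPD, ΔCaT), which drive all alternans
analyses, settle much faster; the scaled-down protocols used by the test
suite and the acceptance script therefore run 150–200 pre-beats per CL.
The residual absolute-APD bias is immaterial against calibration envelopes
~±55 ms wide.

The AP clamp forces Vm along a command waveform (sampled at ≤ 1 ms, linear
interpolation between samples) while all other states evolve freely;
clamping a model with its own steady-state AP is a fixed point of the
calcium subsystem (test-asserted), and clamping an alternans model with two
identical beats (L+L or S+S) probes whether Ca alternans persist without
APD alternans.

## Biomarkers and classification

Per beat: APD at 90% repolarization (ORd convention; the level is
configurable), AP amplitude, peak voltage, RMP (Vm at stimulus onset),
upstroke duration (10→90% of the upstroke), triangulation (APD90 − APD40),
CaT max/min/amplitude, and CaT duration (take-off to 90% recovery).
Crossings are linearly interpolated, making biomarkers sub-sample accurate,
time-shift invariant and stable under grid refinement.

Alternans magnitude is the mean |beat-to-beat difference| of APD (ΔAPD) and
CaT amplitude (ΔCaT) over ≥ 4 recorded steady-state beats; it is invariant
to the (arbitrary) phase of the period-2 rhythm.  A model is an
APD-alternans model when ΔAPD ≥ 5 ms at some CL: Fork-type if alternans
persist at the fastest captured CL (open bifurcation), Eye-type otherwise
(closed bifurcation).  Models with ΔAPD < 5 ms everywhere but ΔCaT ≥ 5% of
mean CaT amplitude are CaT-only alternans models — the 5% is this package's
choice (no absolute threshold is established); it is a configurable
parameter.  Onset CL is the longest CL with ΔAPD ≥ 5 ms, reported at the
protocol's 50 ms resolution without interpolation.

## Population and calibration

Parameter vectors are drawn by Latin Hypercube Sampling over [0, 2]¹¹
(scipy's LatinHypercube; one sample per equal-width stratum per dimension;
seed-reproducible).  Calibration is a per-CL min/max envelope on mean
steady-state APD (a Britton-style envelope calibration): a model is
accepted iff its APD lies inside the envelope at every CL.  The envelope
source is injectable (YAML) so measured ARI envelopes can replace the
synthetic defaults.  Evaluation fuses calibration with the descending CL
ladder: a model that violates its envelope at a long CL is rejected without
simulating the shorter ones — rejection records the first violated CL, and
integration failures are recorded as rejected rows, never dropped.

## Synthetic in vivo data

The calibration data the study design calls for (epicardial sock-electrode
ARI recordings at six CLs) are emulated, not reproduced.  The hierarchical
generator draws ARI(patient, site, CL, beat) = m(CL) + patient effect +
site effect + beat noise, with a fraction of sites carrying period-2 ARI
sequences.  Defaults: 41 patients × 240 sites, patient SD 15 ms, site SD
10 ms, beat noise 3 ms, 10% alternans sites of 12 ms amplitude — spreads of
the order seen in epicardial ARI maps, chosen once; the aggregate spread is
roughly ±70 ms around the mean curve.  The mean curve m(CL) is anchored to
the baseline epicardial model's converged APD90 per CL, which guarantees
the baseline model passes default calibration.  Envelopes are the per-CL
min/max of site-mean ARIs over normal sites.

What the generator does *not* emulate: ARI–APD measurement bias, spatial
correlation between electrodes, pathology-specific rate dependence, or
electrogram far-field effects.  Passing calibration against these envelopes
therefore demonstrates the machinery, and realistic envelope *widths*, not
agreement with any patient data set.

Toy unipolar electrograms encode known activation/recovery times as a steep
negative logistic deflection plus a slower positive-slope T-wave; they are
fixtures for the ARI extraction rule (minimum derivative in a
depolarization window to maximum derivative in a repolarization window;
windows default to 0–80 ms and 100 ms–CL after the stimulus; both are
configurable).  The derivative is lightly smoothed (2.5 ms
boxcar) before extrema detection; extraction is invariant to amplitude
scaling and recovers encoded ARIs to < 1 ms noise-free.

## Calcium balances

SRCB (sarcoplasmic-reticulum Ca balance) is the net Ca gained by the SR
over one beat: ∫(J_up − J_rel) dt with the fluxes volume-weighted to a
common reference (J_up is NSR-referenced and J_rel JSR-referenced in ORd),
expressed in µmol per litre cytosol per beat.  J_up here is the model's net
pump flux (SERCA minus NSR leak), making SRCB exactly the per-beat change
in total SR Ca content.  SCB (sarcolemmal Ca balance) is the net whole-cell
Ca gain across the sarcolemma: ∫(2·I_NaCa − I_CaL − I_Cab − I_pCa) dt ·
A_cap/(2F·V_myo), i.e. the Ca components of the L-type current, background
Ca current and sarcolemmal Ca pump, plus both exchanger components at one
Ca per elementary charge (3 Na⁺ : 1 Ca²⁺ stoichiometry).  Positive = net
Ca gain for both; correlations with alternans magnitude use |balances| of
the short-APD beat, so conclusions are robust to the sign convention.

At a period-1 steady state both balances vanish (asserted to < 1% of the
per-beat release/influx integrals); during alternans, consecutive beats
carry balances of near-equal magnitude and opposite sign (two-beat closure
asserted to < 2%).

## Statistics

Pearson correlation (scipy), partial correlation by OLS
residual-on-residual (each parameter and the biomarker regressed on all
remaining parameters; a rank-based variant is available since the linear
choice is conventional), and the two-sided Mann–Whitney U test.  For total
n ≤ 20 the Mann–Whitney p is exact by enumeration over all group
assignments with midranks — ties are handled, and two identical samples
give p = 1; larger samples use the tie-corrected normal approximation.
Significance stars at 0.05/0.01/0.001; no multiple-testing correction is
applied (raw stars are reported).

## Interventions

Exchanger block rescales s_GNaCa by (1−f), f ∈ {0.2, 0.4, 0.6}, on each
previously classified alternans model, re-runs restitution and
re-classifies.  Conversion percentages are reported over two denominators
(eye+fork only, and all alternans models including CaT-only) because the
phrase "APD alternans models" is ambiguous for the CaT-only group.  The
kinetics study varies one τ at a time over {0.5, 0.75, 1.0, 1.25, 1.5},
measured at a fixed CL (the model's largest-alternans CL), and reports the
linear-fit R² of ΔAPD against |SCB| and |SRCB| across conditions.

## Scaled-down study sizes and reference pools

Full-scale defaults (10 000 LHS models, 500 pre-beats/CL) are kept in
`StudyConfig`.  The shipped test suite and acceptance script run the same
pipeline at desk-scale sizes: 40–50 LHS draws at 150 pre-beats per CL with
4 recorded beats.  Because alternans models are rare (a few percent of
accepted models, and Eye-type under 1%), class-specific analyses use two
frozen reference pools (`cardiopop.presets`): the *complete* alternans
yield of a 500-model LHS screen (10 Fork-type + 1 CaT-only; no curation)
and four Eye-type representatives found by a targeted screen of the
strong-G_CaL/strong-G_NaCa region.  Named single-model presets
(`fork_large`, `eye_large`, …) expose the same vectors for worked examples.

Analysis conventions at this scale:

* per-CL balance–alternans correlations include alternans-class models
  that do not alternate at that CL (they contribute near-zero points);
  this is the only way a correlation exists at the slowest CLs, where few
  models alternate;
* the kinetics study runs on the largest-alternans Eye and Fork models at
  their largest-alternans CL (full multiplier grid in the acceptance
  script, the ±50% extremes in the suite), with the target CL approached
  through the two next-longer CLs of the ladder so each condition lands on
  the attractor a restitution run reaches;
* checks of *absence* of steady-state alternans (kinetics variation on
  normal models) and of two-beat balance closure use 300–500 pre-beats:
  marginal conditions show slowly decaying alternans transients (e.g.
  ~5 ms at 150 pre-beats decaying to <2 ms at 600) and residual
  rate-adaptation drift that would otherwise masquerade as signal;
* group comparisons use the exact small-sample Mann–Whitney test; with
  only a handful of alternans models per population draw they generally
  show the expected median directions but cannot reach the significance a
  2000+-model population would give.

## Known limitations

Single-cell only (no tissue coupling, conduction or discordant alternans);
no β-adrenergic signalling; no stochastic RyR gating or release-unit
spatial structure, so RyR-refractoriness-mediated alternans is outside the
model class by construction; the synthetic in vivo module is a calibrated
fixture, not a forward model of electrograms; and absolute APDs at
scaled-down pre-beat counts carry a few ms of residual rate-adaptation
drift.
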