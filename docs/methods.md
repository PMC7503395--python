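# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `aismature`. The package analyzes the postnatal
maturation of cortical pyramidal neurons from two kinds of raw data —
patch-clamp traces and AIS fluorescence line profiles — and ships synthetic
generators for both, with embedded ground truth, so that every estimator is
testable against a closed form or an independent oracle.

## Passive properties from the seal test

The membrane test is a small voltage-clamp step (default −5 mV) through the
pipette resistance `Rs` into the cell's RC load (`Rm`, `Cm`). The current is

    I(t) = V/(Rs+Rm) + (V/Rs − V/(Rs+Rm)) · exp(−t/τ),   τ = Cm · Rs·Rm/(Rs+Rm).

Estimators (`passive.analyze_seal_test`), kept exactly as they are used in
slice electrophysiology practice:

- `Imem`: mean baseline-subtracted current over the final 20% of the step;
- `Imax`: amplitude of the capacitive transient. The raw sampled extremum
  underestimates `V/Rs` by `exp(−dt/τ)`, which is far from negligible at any
  realistic sampling rate once τ approaches the sampling interval; `Imax` is
  therefore the single-exponential fit **back-extrapolated to step onset**
  (mode `"raw"` retains the sampled extremum).
- `τ`: single-exponential fit of the decay on
  [peak + 2 samples, decay to 5% above `Imem`], log-linear initialization
  followed by `scipy.optimize.curve_fit`; fits with r² < 0.9 are rejected.
- `Rs = |V|/|Imax|`, `R_In = |V|/|Imem|`, `Cm = τ/Rs`.

These definitions carry a documented bias for the ideal RC circuit:
`R_In = Rs + Rm` (the leak path includes the pipette) and consequently
`Cm = Cm_true · Rm/(Rs+Rm)`. The bias is asserted in the tests rather than
hidden; `corrected=True` returns the unbiased `Cm_true` estimate. The
baseline is the mean of the 10 ms immediately pre-step, which makes all
estimates invariant to constant holding current.

For the recovery tests the seal-test record must be long relative to τ
(we use 0.19 s of step for the τ ≈ 6 ms corner of the parameter grid, i.e.
> 30 τ), otherwise the "steady-state" window still contains transient.

## Resting potential and the current-clamp protocols

`Erest` is the mean over a ≥ 50 ms zero-current baseline; a drift > 2 mV
between the first and last fifth of the window raises a warning. Rheobase
protocols step in 5 pA increments (500 ms steps from rest), f–I protocols in
20 pA increments up to 300 pA, matching standard developmental protocols.
Spike detection: upward 0 mV crossings confirmed by a local maximum of
≥ 20 mV prominence within 2 ms (1 ms refractory); frequency is spike count
over step duration, and the input–output gain is the maximum raw finite
difference of the f–I curve (an optional 3-point smoothing exists but is
off by default).

## Phase-plane analysis of single APs

dV/dt is computed by central differences (`numpy.gradient`) on the raw
voltage; V/mV with ms time gives V/s directly. AP threshold is the voltage
at the first upward crossing of 20 V/s before the peak, linearly
interpolated between samples. Half-width is measured at
threshold + (peak − threshold)/2, interpolated on both flanks.

The rising phase (threshold crossing → peak) is decomposed into the
initial-segment (IS) and somatodendritic (SD) components: local dV/dt
maxima with prominence ≥ 10 V/s after Savitzky–Golay smoothing (window 7,
order 3; applied for peak *finding* only). With ≥ 2 maxima the AP is
biphasic — IS is the first (lower-voltage) maximum, SD the absolute
maximum; with one maximum the AP is monophasic and the single component is
attributed to the AIS, as in immature cells.

After-potentials are classified in a window from the downward threshold
recrossing to 100 ms (or the next spike). Because AHP/ADP deflections are
millisecond-scale, the window is low-passed with a 1 ms moving average
before peak finding (recording noise otherwise fabricates ≥ 0.5 mV
"extrema"); amplitudes are then read from the raw trace at the located
extrema, relative to threshold and signed (negative below threshold).
Tri-phasic = minimum (fast AHP), maximum (ADP), later minimum (slow AHP),
each with ≥ 0.5 mV prominence; otherwise mono-phasic with the single slow
AHP amplitude. Windows truncated below 5 ms by the next spike are flagged
unresolved. The measurement window and prominence are configurable since
no community standard exists.

## AIS morphometry

An AIS is measured on a 1-D intensity profile along the axon (positions in
µm from the soma-proximal origin). After a 3-pixel moving average (default
on) and subtraction of the profile minimum (background; default on), the
proximal/distal boundaries are the first and last positions where the
intensity surpasses a threshold **relative to the profile maximum**
(default 30%, per-image override within 10–30% for variable staining),
linearly interpolated between samples. Disjoint suprathreshold runs (e.g.
nodes of Ranvier in the background) resolve to the longest run plus a flag.
Diameter is the FWHM of a perpendicular profile. `extract_profile` samples
a TIFF along a polyline at 1 px arc-length spacing with bilinear
interpolation, averaging across the line width.

The synthetic profile is the analytic model: an ideal plateau convolved
with a Gaussian PSF (so each edge is an error function), sampled on the
pixel grid, plus additive Gaussian noise clipped at zero. The continuous
threshold crossing of that model (additionally convolved with the 3-px
smoothing kernel) is the independent oracle used in the tests; measured
lengths agree with it to within one pixel across PSF σ ∈ {0, 0.2, 0.4,
0.6} µm and thresholds 10–30%, and to ~0.05 µm for σ ≥ 0.2 µm. Note that a
*sub-pixel discontinuity* (σ = 0) can never be localized better than the
straddling pixel by interpolated crossings; with realistic PSFs the
localization is effectively sub-pixel.

## Derived biophysics

- AIS capacitance: open cylinder, `C_AIS = π · d · L · c_m` with specific
  membrane capacitance `c_m` defaulting to 1 µF/cm² (0.01 pF/µm²) — the
  textbook value; configurable and recorded in the output. Group-level
  `C_AIS` uses the per-group mean measured length and diameter.
- Estimated AIS inward current: `Est I_In-AIS = C_AIS × IS`, exact in units
  (pF × V/s = pA).
- Rheobase–R_In relation: Ohm's law predicts `rheobase = V / R_In` with `V`
  the depolarization needed to reach threshold from rest. The one-parameter
  least-squares fit in current space has the closed form
  `V = Σ(I_i/R_i) / Σ(1/R_i²)`. Empirically `V` should match
  `threshold − Erest` per cell; both are computed. Because the detected
  rheobase is quantized upward by the 5 pA protocol, the fitted `V` carries
  a positive bias bounded by `5 pA · Σ(1/R_i)/Σ(1/R_i²)`, which the
  end-to-end tests propagate explicitly.

## Group statistics

Units of analysis follow replicate structure: individual neurons are
biological replicates for electrophysiology; for AIS morphometry the
technical replicates (hundreds of AIS per animal) are averaged so the
animal is the unit. Each group is Shapiro–Wilk tested at α; if **all**
groups pass, one-way ANOVA with Bonferroni-corrected pairwise t tests,
otherwise Kruskal–Wallis with Dunn's test (z on pooled mean ranks with tie
correction, Bonferroni-adjusted). Dunn's test is implemented in
`group_stats.dunn_test` (it is a short closed form; for two groups its z²
equals the Kruskal–Wallis H, which the tests exploit as a cross-check).
Post hoc tests run only when the omnibus test is significant (configurable).
The type-I error of the whole branched procedure is simulated under the
null (5 groups × n = 20, 1000 replications) and stays within [0.03, 0.07]
at nominal α = 0.05. Stars follow the usual convention (* p < 0.05,
** p < 0.01, *** p < 0.001); summaries report median/IQR/min–max (box
style) or mean ± SD (XY style).

## Synthetic generators

All generators take an explicit seed, use no global random state, and
embed their ground truth in the returned object (`meta` or manifest), so
recovery tests never infer truth from the signal.

**Seal test** — the closed-form RC current above plus Gaussian noise.

**LIF step responses** — subthreshold voltage is the exact closed form
`Erest + I·R_In·(1 − exp(−t/τ))`; at each threshold crossing a stereotyped
AP is pasted (half-cosine rise to +30 mV, half-cosine fall over 2 ms to the
reset at `Erest`), then integration restarts. The rise time can be set from
a target peak dV/dt, which lets cohorts carry realistic, age-dependent IS
components on otherwise stylized spikes. The continuous rheobase
`I* = depol / (R_In (1 − e^{−T/τ}))` is recorded as ground truth. The LIF
arm is used for rheobase/f–I logic and threshold/after-potential plumbing,
not for biophysically detailed waveforms.

**Two-compartment conductance model** — soma and AIS coupled by an axial
conductance; per compartment `C dV/dt = −g_L(V−E_L) − g_Na m∞³(V) h (V−E_Na)
− g_K n⁴ (V−E_K) ± g_ax ΔV + I_inj`, with instantaneous Na activation and
first-order h and n. Defaults (chosen once, before any acceptance
measurement, and fixed): C_soma 40 pF, C_ais 2 pF, g_ax 60 nS, gNa_ais
600 nS vs gNa_soma 150 nS, AIS Na activating 11 mV more hyperpolarized than
somatic (−39 vs −28 mV half-activation, slope 6), h: half −45 mV, slope 6,
τ 1.5 ms; n: half −25 mV, slope 9, τ 3 ms; leak to −75 mV. The small,
sodium-dense AIS fires first and pre-charges the soma through the axial
conductance — that is the IS hump of the somatic phase plot — and somatic
sodium then produces the SD peak. Setting gNa_soma = 0 yields a monophasic
(IS-only) phase plot; raising gNa_ais from 400 to 800 nS raises the IS/SD
ratio strictly monotonically. Integration is fixed-step RK4 at 0.005 ms
(≤ 0.01 ms enforced; halving dt changes peak dV/dt by < 1%, and per-
compartment charge balance closes to 0.1%); |V| > 200 mV raises a stability
error naming the step size.

**Cohorts** — five default age groups (first postnatal week to > 5 months)
with per-group Normal distributions for Cm (60 → 190 pF), Rm (600 →
140 MΩ), Erest (−58 → −70 mV), AIS length (14 → 28 µm with > 80% of the
elongation designed to occur by the third week), diameter (1.0 → 1.5 µm)
and IS dV/dt (90 → 300 V/s); threshold depolarization is held at 16 ± 2 mV
across ages so threshold hyperpolarizes in lockstep with Erest. Group sizes
follow the study design (4–5 animals and ~20–25 cells per group; 100 AIS
per animal). Every cell gets a seal test, a 5 pA rheobase protocol
(adaptively topped a few steps above its true rheobase, as bench protocols
do), a 20 pA f–I protocol and an AIS profile; the AIS arm adds per-animal
profile sets. Measurement noise defaults: 5 pA on seal tests, 0.15 mV on
voltage, 3% of plateau on profiles.

### What the generators do *not* emulate

- Channel noise, adaptation, bursting, sag; electrode artifacts and
  capacitance compensation errors.
- The LIF spike is pasted, so its repolarization (and hence min dV/dt and
  the mono-phasic AHP equal to the reset depth) is stereotyped; tri-phasic
  after-potentials arise only from the two-compartment model or real data.
- Maximal firing frequency in the LIF cohort *decreases* with the adult
  parameter set (lower R_In → slower approach to threshold under the same
  protocol ceiling), opposite to the biological maturation trend; this
  variable is therefore not part of the cohort's directional contract.
- Images are straight, single AISs; no 3-D stacks, no crossing processes.

Passing tests therefore demonstrate correctness of the estimators and the
internal consistency of the pipeline on data whose generating model is
known — not robustness to every pathology of real recordings.

## Problem sizes in the shipped runs

The default test suite and `scripts/acceptance.py` run everything at desk
scale, chosen as the sizes above: the 5×5×5 passive grid, 100 random LIF
cells, 5-point conductance sweeps, 12 profile conditions, 40-cell hyperbola
cohorts, 1000-replication type-I simulations, and the 113-cell/2300-AIS
five-group cohort. The full suite finishes in about a minute; the
acceptance script in well under a minute.
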