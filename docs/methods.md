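# Methods

This note documents the models, measurement conventions, numerical choices
and known limitations behind `patchkit`. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## The analysis problem

Whole-cell patch-clamp studies of iPSC-derived dopaminergic neurons compare
control and patient (e.g. sporadic PD or GBA1-variant) cohorts on a small set
of per-cell features:

* **evoked excitability** — the total number of action potentials over a
  family of 400 ms current injections in 3 pA increments, starting 12 pA
  below the holding current that keeps the cell at −60 mV, counted over the
  first 32 steps;
* **spontaneous synaptic activity** — rate and mean amplitude of EPSCs
  detected in gap-free voltage-clamp recordings at −60 mV, plus the rate of
  "large" events (> 30 pA, strict inequality) and pooled amplitude ECDFs per
  group;
* **passive properties** — capacitance from the membrane-test transient and
  input conductance from the holding currents at −70 and −50 mV
  (ΔI / 20 mV);
* **voltage-gated currents** — Na and fast/slow K current densities (pA/pF,
  normalized by capacitance) from 400 ms voltage steps spanning −90..+80 mV
  from a −60 mV hold, compared across groups in the −20..0 mV band (Na) and
  +50..+90 mV band (K).

All recordings are represented on a fixed 20 kHz grid. Units throughout:
ms, mV, pA, nS, pF, pA/pF.

Because patient recordings are not redistributable, the package pairs the
analysis code with a forward model that generates all four recording types
for hierarchical control/case cohorts with known ground truth. Every
analysis stage is validated against that ground truth.

## Synthetic neuron model

A single-compartment conductance-based cell:

C dV/dt = −g_L(V−E_L) − g_Na m³h(V−E_Na) − g_Kf a³b(V−E_K) − g_Ks n(V−E_K) + I_inj

Each gate is first-order with a Boltzmann steady state
x_∞(V) = 1/(1+exp(−(V−V_half)/k)) and a **fixed time constant**. Fixed τ
values make gates exactly integrable at constant voltage, so ideal-clamp
voltage-step families are computed in closed form (no integration error);
they give up the voltage-dependent kinetics of Hodgkin–Huxley rate
functions, which none of the implemented measurements depend on.

Default parameters (the "standard cell", chosen once for realism: resting
near −60 mV, input conductance a few nS, ~+35 mV spike overshoot, Na peak
density ~−170 pA/pF peaking near −10 mV, early-peaking then sustained
outward K):

| parameter | value | | gate | V_half (mV) | k (mV) | τ (ms) |
|---|---|---|---|---|---|---|
| C_m | 25 pF | | m (Na act.) | −40 | 5 | 0.15 |
| g_L, E_L | 2 nS, −65 mV | | h (Na inact.) | −50 | −6 | 4 |
| g_Na, E_Na | 90 nS, +60 mV | | a (fast-K act.) | −27 | 12 | 1.5 |
| g_Kf | 40 nS | | b (fast-K inact.) | −65 | −8 | 30 |
| g_Ks, E_K | 30 nS, −90 mV | | n (slow-K act.) | −15 | 10 | 25 |

* **Voltage clamp** (series resistance 0, the default): gates follow their
  exact exponentials per constant-voltage segment; the capacitive transient
  collapses to a one-sample impulse carrying charge C·ΔV at each edge.
  With series resistance > 0 the membrane ODE is integrated explicitly and
  the membrane test uses the analytic RC cascade
  (τ = C·R_s·R_m/(R_s+R_m)).
* **Current clamp**: exponential-Euler updates at dt = 0.025 ms (2×
  oversampling of the 20 kHz output), in a numba kernel. The holding
  current is solved from the steady-state I–V at −60 mV; a non-increasing
  I–V there is rejected as having no stable holding point.
* **Synaptic traces**: Poisson event times, log-normal amplitudes (default
  median 22 pA, log-SD 0.55, rate 1.5 Hz), each event adding a unit-peak
  bi-exponential inward kernel (τ_rise 1 ms, τ_decay 6 ms) on the holding
  current at −60 mV. Noise is Gaussian, low-pass filtered at 1 kHz and
  rescaled to the requested SD (default 3 pA) — matching the visual texture
  of recorded baselines while keeping the SD exact.

## Cohorts

A cohort is groups → lines → cells. Cell parameters are group base values ×
group effect multipliers × mean-one log-normal factors drawn per line
(CV 0.1) and per cell (CV 0.25). Multiplicative log-normal variability keeps
parameters positive and mimics between-line heterogeneity of iPSC panels.
Seeding is content-addressed (`SeedSequence((master_seed, group, line, cell,
purpose))`), so adding a cell never changes any other cell's data and every
output is a pure function of (spec, seed).

The canonical disease-like cohort (`phenotype_cohort_spec`) has 3 lines × 20
cells per group and case effects g_Na ×0.5, EPSC rate ×0.5, amplitude ×0.6 —
the direction and rough size of the published patient phenotypes. Its
gap-free traces are 45 s per cell, long enough for stable per-cell rate
estimates at ~1.5 Hz while keeping 20-replicate studies to minutes;
detection-fidelity studies use 120 s traces.

What the generator does **not** emulate: electrode drift and seal
instability, access-resistance changes over a session, non-stationary event
rates, multi-compartment filtering of synaptic currents, temperature
effects, channel stochasticity. Passing tests therefore demonstrate
correctness of the measurement code under clean, stationary conditions —
not robustness to every pathology of real recordings.

## Measurement conventions

* **Spikes**: upward crossings of 0 mV with a 2 ms lockout (optional dV/dt
  gate). Parameter-light and robust for overshooting spikes; counts are
  summed over step windows of the first 32 sweeps.
* **Capacitance**: C = Q/ΔV with Q the integral of (current − steady) over
  the step; estimates averaged over 8 membrane-test sweeps. An unresolvable
  transient (below 3× baseline noise) raises instead of returning garbage.
* **IV extraction**: per sweep, baseline = mean of the 50 ms before onset;
  0.5 ms capacitive blank; Na = window minimum over onset+blank..10 ms
  (clipped ≤ 0); fast K = window maximum over ..25 ms (clipped ≥ 0); slow
  K = mean of the last 50 ms of the step (clipped ≥ 0); densities divided by
  the measured capacitance.
* **Passive correction** (default `"template"`): the averaged
  baseline-subtracted waveform of the −90..−70 mV steps, normalized per mV,
  scaled to each test step and subtracted — the P/N idea. This removes
  leak, the instantaneous driving-force jump of channels standing open at
  the −60 mV hold, and the capacitive transient; a purely linear cell
  yields exactly zero densities. A steady-state linear fit
  (`"linear"`) and no correction (`False`) are selectable. Residual
  contamination of the Na window by fast-K activation within the first
  ~1–2 ms remains (it is a real measurement property, not removable by any
  passive correction); it bounds the Na band linearity error at a few
  percent at strong g_Na reductions.
* **EPSC detection** (default `"template"` backend): baseline removal by
  running median (200 ms window, computed on a 50× decimated grid), 1 kHz
  zero-phase low-pass, sign inversion, then least-squares projection onto
  the unit-peak bi-exponential template at every lag — the projection *is*
  an amplitude estimate in pA. Local maxima above
  max(4 × robust noise SD, 5 pA) become events; candidates closer than 5 ms
  merge into the larger one so template ringing cannot inflate rates.
  Noise SD is 1.4826 × MAD of the baseline-subtracted trace, insensitive to
  sparse events. A plain threshold-crossing backend (one event per
  supra-threshold excursion, gap-based coalescing) is available for
  comparison. With the defaults and 3 pA noise the absolute floor implies
  events below ~12 pA are not detectable; both groups are truncated
  identically, so group contrasts remain interpretable, but detected mean
  amplitudes are biased upward relative to the true event population.

## Statistics

Scalar features: two-sided Mann–Whitney U (midrank ties); the p-value is
exact (full enumeration) for pooled n ≤ 16 without ties, otherwise the
normal approximation with tie and continuity corrections. Current
densities: one-way ANOVA per voltage step inside the canonical bands plus a
band-mean ANOVA, preceded by Lilliefors-corrected KS normality checks
(plain KS against a fitted normal is anticonservative) and Levene's
variance-homogeneity test. Group summaries are mean ± SEM (SD/√n); stars
at p < 0.05/0.01/0.001/0.0001. Per-step p-values are reported raw by
default; Benjamini–Hochberg adjustment is available as an option.

Pooled amplitude ECDFs are compared for the characteristic left shift of
case groups with a one-sided Kolmogorov–Smirnov bound
(`ecdf_left_shift`): strict pointwise dominance of two *empirical* CDFs
from independent samples fails with high probability wherever the true gap
is small — in particular just above the shared detection threshold, where
both truncated distributions restart at zero — even when the underlying
distributions are strictly ordered. The check therefore requires that the
largest dominance violation stay below the one-sided KS sampling deviation
at α = 0.05; a genuinely non-left-shifted case group still fails it. (For
the degenerate case of one sample rescaled, strict dominance holds exactly
and is tested exactly.)

Two deliberate choices:

* **Levene's test is median-centered** (Brown–Forsythe). On the strictly
  positive, right-skewed features this pipeline produces, the mean-centered
  variant is anticonservative (empirical size ≈ 0.07 at n = 30/30 in this
  package's own calibration); the median-centered variant holds its nominal
  size and is the standard robust recommendation. `center="mean"` restores
  the classical test.
* **Cells are the unit of analysis**, matching standard practice in this
  literature. With only a few donor lines per group, line-level random
  effects make cells correlated and all reported p-values anticonservative
  with respect to donor-level inference. The package does not correct for
  this; calibration studies therefore use cohorts with zero between-line
  variability (exchangeable cells), which is the regime in which the tests
  themselves can be calibrated. Hierarchical/mixed-effects modeling is out
  of scope.

## Pipeline

`simulate → extract → compare` runs from one YAML/JSON config with a master
seed. Runs are reproducible byte-for-byte (feature tables, event tables,
reports; JSON keys sorted, no timestamps outside logs). The dataset
manifest records a canonical content digest per recording — HDF5 object
headers embed creation times, so raw file bytes are not run-stable but the
stored content is — and reports embed the config and manifest hashes.
Extraction is fail-soft: a corrupt cell is logged to `qc.json` with its
error and the cohort continues.

## Problem sizes used in validation

Chosen as the package's own study sizes: statistical calibration uses 2000
feature-level null cohorts of 30 cells per group; detection fidelity uses
20 × 120 s traces at 3 pA noise (plus 15 traces across rates 0.5/1.5/3 Hz);
phenotype reproduction uses 20 cohorts of 60 cells per group (45 s gap-free
traces); determinism uses a 12-cell demo cohort run twice.

## Known limitations

* Fixed gate time constants; no voltage-dependent kinetics.
* Single compartment; no dendritic filtering of synaptic events.
* Detection floor truncates the amplitude distribution (above).
* Evoked AP counts and Na densities respond to g_Na nonlinearly near spike
  failure — intended (it is the biology) but means effect multipliers do not
  map 1:1 onto feature ratios.
* No correction for within-line correlation (see Statistics).
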