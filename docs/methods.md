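# Methods

## Background and scope

A subretinal visual implant replaces lost photoreceptor function with a
microphotodiode array (MPDA): each of its 1500 pixels converts local
luminance into a rectangular anodic voltage pulse (1 ms, repeated at the
5 Hz working frequency) that stimulates the remaining retinal network. The
pulse amplitude as a function of log10 luminance — the transfer
characteristic curve — is sigmoidal, with a steep graded region of roughly
two log10 units between a subthreshold floor and a saturation ceiling. Two
control voltages on the patient's handheld unit, exposed as integer knobs
0–99, reshape the curve: the sensitivity knob (V_gl) translates it along the
log-luminance axis, the gain knob (V_bias) scales the maximal output.

Because the stimulation currents spread through the eye, each chip pulse is
visible at the cornea. Recording these corneally recorded implant responses
(CRIRs) with a standard ERG setup during a series of full-field flashes of
increasing luminance recovers the transfer curve *in vivo*. This package
simulates that entire measurement chain and implements the analysis,
settings-selection and fault-triage procedures that operate on it.

## Implant model

The transfer curve is a four-parameter logistic in x = log10 L:

    V(L) = v_min + (v_max − v_min) · σ(slope · (x − x_mid)),   σ(u) = 1/(1+e^{−u})

The true knob-to-voltage maps of the handheld unit are set per patient and
not public, so the knob maps are declared calibrations (a swappable
`Calibration` object) chosen to reproduce the clinically described behavior:

* **Midpoint:** x_mid = −1.0 + 4.5·v_gl/99, so the knob range sweeps the
  curve across the 4–5 log units of luminance CRIR measurements cover.
* **Gain:** v_max = 2.0 V · exp(−((v_bias − 65)/30)²). The in-vivo maximal
  output is unimodal in v_bias with its optimum at knob value 65, inside the
  typical 55–75 window; both lower and higher settings reduce the output.
  The peak chip amplitude of 2.0 V is calibrated so that the largest corneal
  response is 35 mV (below).
* **Dark output:** above v_bias = 70 the subthreshold floor rises
  quadratically (0.6 · 2.0 V · ((v_bias−70)/29)² , capped at half the
  setting's own v_max). This makes high-gain settings show the "elevated
  output at low luminances" pattern the advisor must reject.
* **Slope:** the dimensionless slope ln 9 ≈ 2.197 puts the 10–90% dynamic
  range at exactly 2.0 log10 units. The gain knob is described clinically
  as changing "the slope and the maximal output"; we model this as vertical
  scaling — the steepness in **V per log unit** scales with (v_max − v_min)
  while the dimensionless slope stays fixed, so the dynamic range in log
  units is setting-independent. The alternative (scaling the dimensionless
  slope itself) would contradict the fixed ≈2-log-unit graded region and
  make low-gain curves unfittably flat.

All 1500 pixels are treated as identically illuminated (full-field
stimulation); spatial structure and photodiode physics are out of scope.

## Stimulus protocol

Default: 9 flashes of 350 ms from 0.1 to 1000 cd/m², 0.5 log10 steps. The
inter-step interval (2 s) and the 1 s lead-in are our choices — long enough
for the 0.312 Hz high-pass to settle and for a clean 50 ms pre-pulse
baseline. The chip free-runs, so the pulse-train phase relative to flash
onset is a parameter (default 0); at 5 Hz and 350 ms each flash holds one or
two pulses depending on phase.

## Signal chain

* **Coupling:** the capacitive electrode–tissue interface is modeled as a
  single-pole high-pass, discretized exactly
  (y[n] = e^{−Δt/τ} y[n−1] + x[n] − x[n−1], τ = 0.5 ms): a rectangular pulse
  yields a dominant anodic lobe, an opposite-sign overshoot after offset, an
  exponential return to baseline and zero net area (charge balance). The
  real chip-to-cornea transfer depends on many tissue factors; this
  single-pole model is a declared simplification. The attenuation 0.0175
  is calibrated so the grid-maximum corneal amplitude is 35 mV.
* **Amplifier/ADC:** gain 10, hard clip at ±0.5 V, uniform 16-bit
  quantization; samples returned referred to input. The 12-bit DC offset
  register is carried as metadata (default 0). Consistency check: 35 mV × 10
  = 350 mV < 500 mV, so the stated specs never clip.
* **Band-pass:** "second-order cascaded Bessel" is realized as HP(2nd order,
  0.312 Hz) × LP(2nd order, 300 Hz), each magnitude-normalized (−3 dB at the
  nominal cutoff) and discretized by the bilinear transform with prewarping
  at the cutoff. Filtering is causal single-pass, matching online clinical
  acquisition; the recorded CRIR is therefore a delayed, broadened, biphasic
  version of the 1 ms pulse. Measured −3 dB points of the realized filter:
  0.3117 Hz and 300.27 Hz (both within 0.1% of nominal). For a 1 ms pulse
  the bilinear realization's peak differs from direct convolution with the
  analog cascade's impulse response by ≈1.3% (the pulse spectrum reaches the
  prewarping region); for a 10 ms pulse the difference is ≈0.1%. Tests
  assert 3% and 0.5% respectively.
* **Noise/artifacts:** seeded white Gaussian noise (default 20 µV RMS
  referred to input — keeps the smallest CRIRs detectable while making
  detection nontrivial) plus optional blink transients (Gaussian bump) and
  dropouts (flatline), injected after the filter as the final stage, with
  ground-truth windows in the trace metadata. Physiological ERG components
  are absent by design: in end-stage retinitis pigmentosa the corneal signal
  is implant-only.

## Analysis

Pulse windows are stimulus-locked: expected onset ± 20 ms (absorbing the
few-ms filter delay), with a 50 ms pre-window baseline — both chosen
relative to the 200 ms frame period to avoid overlap. Amplitude is the
first-lobe peak minus the baseline median (peak-to-peak available as a
config option; which convention the clinic used is not documented).
Flags: `clipped` (≥2 consecutive rail samples), `artifact` (baseline
peak-to-peak beyond max(12×noise RMS, 1 mV), or a ≥5 ms flatline run when
noise is present), `low_snr` (amplitude < 5×noise RMS). Artifact/clipped
pulses are excluded from the per-step mean; `low_snr` pulses are kept —
their near-zero amplitude *is* the subthreshold measurement. A step with no
usable pulse is marked for repeat and merged from a repeat recording when
supplied, mirroring the clinical artifact-repeat rule.

The sigmoid fit is bounded least squares on (v_min, v_max−v_min, x_mid,
slope) with v_min, span ≥ 0 and slope ∈ [0.01, 50]; initialization from the
amplitude extremes, the half-range crossing and the endpoint secant, plus
5 seeded jittered restarts. Non-convergence and degeneracy (flat data) are
reported as flags, never raised. Region bounds are the fitted 10%/90%
output crossings ("steep part" is not quantified clinically; 10–90% is our
convention); the bounds themselves classify as slope (closed interval). A
luminance pair is resolvable iff both members classify as slope.
Non-monotone amplitude sequences beyond 8× the median absolute residual
raise a data-quality warning (median, not RMS, so an outlier cannot mask
itself).

## Advisor and triage

A curve qualifies for an ambient range [lo, hi] when its slope region
contains the range and its fitted output at the dark reference luminance
(default 0.01 cd/m²) is at most 10% of the family-wide maximum output (the
clinic gives examples of "elevated dark output" but no number; 10% is our
threshold). Among qualifying curves the lowest saturation output wins
(lowest necessary stimulation voltage); ties break toward lower dark
output, then lower v_bias. Reason codes: `no_coverage` (including
unusable fits), `elevated_dark_output`, and `high_saturation_output` — the
last is an ambient-independent absolute output cap (`max_saturation_v`,
off by default). This keeps the qualifying set a partition complement of
the rejected set and monotone under ambient shrinkage; the
prefer-lowest-output rule is expressed in the choice, not in rejection.

Fault triage uses per-gaze-direction amplitude sets with detection
threshold 5× noise RMS: output absent everywhere → `device_output_absent`
(damaged wire); output in some gaze directions only, or intermittent
across repeats within a direction → `gaze_dependent_intermittent` (loose
connection); otherwise `device_functional`, with a note that persisting
perceptual problems then point to biological causes outside device scope.
"Intermittent" as detection varying across repeats is our
operationalization of the clinically described "non-regular signal".

## Synthetic data and what it does not show

`crir.fixtures.generate_fixture` realizes seven seeded scenarios through
the full forward chain (settings families, sensitivity/gain sweeps,
elevated dark output, dead device, loose connection, artifact-heavy
session). The generator reproduces the protocol, device constants and
recording chain above; it does **not** model patient-to-patient coupling
variability, electrode impedance drift, mains interference, eye movements
during a step, or any residual physiological signal. Passing tests
therefore demonstrate correctness of the measurement and decision logic
under the stated device model, not robustness to every clinical recording
condition. Fault-triage fixtures use a shortened 3-step protocol per gaze
direction to keep run times proportionate; the decision rules operate on
amplitude sets and are protocol-length independent.

## Numerical choices and problem sizes

Quantization error is ≤ ½ LSB by construction; all tolerances used in tests
are stated there. The −3 dB measurement sweeps 6000 log-spaced frequencies
and bisects the crossings. Parameter-recovery checks use 50 seeded noisy
replicates of the 9-step protocol (median |x_mid| error < 0.15 log units,
median relative v_max error < 5% against the noiseless reference); triage
checks run 50 seeds per fault scenario. The headline-quantity script sweeps
a 15×15 knob grid plus the calibrated optimum for the amplitude bound and
all 100 v_bias values for the gain-optimum sweep.

## Known limitations

* All knob maps are calibrations, not measured device properties; per-
  patient individualization is supported by swapping the `Calibration`.
* The single-pole coupling model collapses a multi-factor tissue pathway
  into two constants; simulated corneal waveforms match the described
  morphology qualitatively, not any patient quantitatively.
* The exact topology of the recorder's "second-order cascaded Bessel"
  filter is not documented; HP×LP with magnitude normalization matches the
  stated cutoffs and is the implemented interpretation.
* CRIR amplitude is not linked to perceptual thresholds; no perceptual
  model is included.
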