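# Methods

This note documents the models, defaults and numerical choices behind
`ihcsynapse`, and what the synthetic-data validation does and does not
establish about real recordings.

## Forward model of a synthetic experiment

Each synthetic cell carries an elliptical boundary (default semi-axes
42 × 26 px at 103 nm/px), a set of active-zone hot spots placed inside the
ellipse, and per-synapse parameters drawn once from population
distributions (`GradientParams`).

**Ca²⁺ influx.** Channel gating is a two-parameter Boltzmann
`P(V) = 1/(1 + exp((V₁/₂ − V)/k))`; the Rhod-FF fluorescence change is the
driving-force-weighted form `ΔF(V) = g_max·(V − V_r)·P(V)` with
V_r = +47.6 mV fixed and g_max < 0 by convention, so ΔF is positive below
the reversal potential. Note that ΔF(V) peaks near −28 mV for typical
parameters — activation saturates while the driving force keeps shrinking —
so step responses are strictly monotone in voltage only below that peak and
decline by a few percent between −25 and −17 mV. This is a property of the
model itself, and the tests assert exactly that shape.

**Release.** The instantaneous release rate carries the cooperativity
power law, referenced at the pool-protocol potential (−23 mV):
`λ(V) = (1/τ_dep)·(ΔCa(V)/ΔCa(−23 mV))^m`. Cumulative release over a step
of duration T is `Q(V,T) = RRP·(1 − e^(−λ(V)·T)) + s(V)·T`, with the
sustained rate sharing the same Ca²⁺ dependence
(`s(V) = s_ref·(ΔCa/ΔCa_ref)^m`; sustained exocytosis is also Ca²⁺-driven).
Two consequences follow: a duration series at −23 mV obeys exactly the
exponential-plus-line the pool fit assumes, with τ equal to the synapse's
`tau_depletion_ms`; and across voltages the sub-saturation relation between
release and Ca²⁺ signal is an exact power law with exponent m.

**Indicator and camera.** The iGluSnFR response to a step is the double
exponential `A·(1 − e^(−t/τon))·e^(−t/τoff)` scaled by Q(V,T); Rhod-FF (a
fast low-affinity indicator) follows ΔF(V(t)) instantaneously. Hot spots
are symmetric 2-D Gaussians (σ = 4 px); out-of-focus planes attenuate spot
amplitude by a Gaussian in z whose default FWHM (1.55 µm) loses 25% at
±0.5 µm, matching the plane spacing's empirical loss. The iGluSnFR channel
bleaches mono-exponentially (default τ = 20 s, restarting per recording);
both channels receive an additive 33.3 Hz sinusoid (the spinning-disk
artifact), shot noise modeled as Gaussian with variance = signal/gain (the
large-count approximation of Poisson noise), and Gaussian read noise.

**Population defaults** (chosen once; none are claims about new data):
V₁/₂ = −45 mV at the pillar end rising by +8 mV per unit position toward
the modiolar end with 3 mV scatter — pillar synapses activate at more
negative potentials, and the composite distribution lands near
−41 ± 5 mV; k ~ N(5.0, 0.7) mV; m drawn from a three-component mixture at
1.6 / 3.2 / 6.1 (weights 0.50 / 0.35 / 0.15) echoing the nanodomain /
intermediate / microdomain phenotypes; RRP ~ N(2.3, 0.5) a.u.
(≈ 10 vesicles × 0.23 a.u./vesicle); τ_dep ~ N(11, 2) ms; sustained rate
~ N(42.7, 8) a.u./s; τon ≈ 10 ms, τoff ≈ 90 ms with 15% relative scatter.
Hot spots are kept ≥ 14 px apart by default so segmentation failures are
attributable to the segmenter (the separation relaxes automatically for
crowded cells).

## Analysis pipeline

Per cell: ΔF image (mean of 5 response frames minus mean of 15 baseline
frames) → Gaussian filter (σ = 2; a 4–6 px median filter is the
single-color alternative) → maximum-entropy threshold → watershed →
bouton/hot-spot ROIs (≥ 20 px); a 60 × 60 px background region on the
pillar-side edge, slid along the edge until it overlaps no ROI; per-ROI
traces background-subtracted and normalized to the 15-frame baseline
(ΔF/F₀); the 100 Hz channel notch-filtered at 33.3 Hz; photobleaching
removed by an exponential fit excluding the 40-frame response window; AUC
as the trapezoidal area over 40 frames; fits as in the README. Boutons and
Ca²⁺ hot spots are paired by centroid distance (≤ 10 px). Fits with
R² ≤ 0.7 are flagged and excluded from clustering. The best plane per hot
spot is the argmax of ROI-mean ΔF across planes, ties resolved toward the
stack center.

### Numerical choices

* **Maximum-entropy threshold**: Kapur's criterion on a 256-bin histogram
  spanning the image range; the returned threshold is the upper edge of
  the argmax bin. Thresholds inside a run of empty bins are equivalent
  classifiers; tests therefore compare the induced pixel partition, not
  the float value.
* **Watershed seeds**: local maxima of the *filtered intensity* inside the
  mask (min separation 3 px), flooding the negative intensity. Seeds from
  the distance transform cannot split two touching spots — their union is
  convex, so its distance transform is unimodal — whereas intensity keeps
  one peak per synapse.
* **Notch filter**: zero-phase (forward–backward) IIR notch, Q = 8. A
  wider notch visibly smears the 150-ms ramp transient and inflates the
  fitted slope factor k by tens of percent; at Q = 8 the line is removed
  completely (> 250 dB at 33.33 Hz after filtfilt) with < 0.05 dB ripple
  below 10 Hz.
* **Bleach correction**: `b₀·e^(−t/τ) + c` fitted to the off-response
  samples. The constant offset is required: with multiplicative bleaching
  of the raw fluorescence, the ΔF/F₀ baseline is an exponential plus a
  constant, and an offset-free model cannot zero the corrected baseline.
  Non-convergent fits fall back to a linear trend (logged).
* **Boltzmann and power fits**: trust-region least squares; V₁/₂
  initialized at the half-maximum crossing (multi-start for the ramp fit),
  k at 5 mV; the power fit runs in linear space with the log-log slope as
  initialization. The Ca²⁺ fit never fits V_r; a positive fitted gain is
  flipped to the negative convention with a warning.
* **AUC**: trapezoidal rule over a fixed 40-frame window with the frame
  duration factored in (a.u.·s); a time-based window is available for
  rates other than 50 Hz.
* **Pool fit**: `RRP·(1 − e^(−t/τ)) + slope·t`. The exponent is negative —
  a growing exponential cannot describe depletion saturation.
  `fit_slope=False` constrains the sustained term for purely saturating
  data, where the three-parameter model is poorly identified. On a pure
  line the exponential term is unidentifiable (τ → ∞ mimics a line); the
  well-determined quantity is the initial rate `slope + RRP/τ`.
* **Clustering**: the 11 properties are z-scored before K-means and PCA
  (mixing mV and a.u. unscaled would be meaningless); K-means uses seeded
  k-means++ with 10 restarts, and clusters are renamed by ascending
  centroid m, which makes labels reproducible across seeds for separable
  data. The 11-property list is recorded in every run manifest and is
  configurable.
* **Axis position**: orthogonal projection of the hot-spot center onto the
  major axis, normalized pillar (0) → modiolar (1) and clipped; which end
  is "pillar" is a per-recording configuration, since it is fixed by the
  recording approach, not by the image.

## Apparent versus rate-law cooperativity

The measured m comes from fitted curves: a Boltzmann through the per-step
release amplitudes against the fitted Ca²⁺ curve, restricted to release
≤ 25% of maximum. Even noiselessly this estimator returns less than the
rate-law exponent, because pool depletion compresses the upper part of the
fit range (λT reaches ~0.4 at the cutoff for typical parameters, bending
the relation by ~15–20%). This is intrinsic to any dose-response estimate
of cooperativity under depletion, not an implementation artifact.
Parameter-recovery tests therefore compare pipeline estimates against
`apparent_cooperativity_truth` — the identical estimator run on the exact
closed-form responses — while the estimator itself is validated separately
on constructed exact power-law pairs, where it recovers m to three digits.

## Validation scales and what they show

The default test suite and the acceptance script use: 110 synapses for
trace-level recovery (median |ΔV₁/₂| ≈ 0.3 mV, k ≈ 6%, m ≈ 10% at
movie-equivalent noise); a full 34-cell / 55-synapse rendered study for
end-to-end recovery, the position gradient and clustering (completes in
tens of seconds on one CPU); 40 two-spot images at peak SNR 10 for
segmentation; and 100 random draws for each oracle-equivalence check.
Trace-level noise levels are calibrated to what the movie renderer's
default shot/read noise produces after ROI averaging (AUC SD ≈ 1.2% of the
maximal response, measured by repeated renders). Bleach-τ recovery uses
3-s traces with τ = 1–2.5 s: a 1.2-s sweep cannot identify a 20-s time
constant (the exponential is locally linear), and inside the pipeline only
the fitted trend — not τ — enters the AUC.

## Limitations

The generator emulates the statistical structure the analysis assumes —
Gaussian spots, a clean elliptical cell, stationary hot spots, exact
power-law coupling, mono-exponential bleaching — and omits motion,
spillover between neighboring synapses, diffraction, indicator saturation
and dark/flicker states. Passing recovery tests therefore demonstrates
that the pipeline measures what the model generates at realistic noise; it
does not certify performance on pathologies the model excludes. Whole-cell
capacitance is consumed as a trace (the ΔC_m window arithmetic); the
lock-in estimation of C_m from raw current is out of scope, as are motion
correction, registration and immunolabel-based ribbon confirmation (the
bouton–ribbon correspondence check is reduced to the bouton/hot-spot
distance gate).
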