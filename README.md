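# ihcsynapse

Single-synapse analysis of inner-hair-cell (IHC) active zones from
dual-color fluorescence imaging and patch-clamp electrophysiology — with a
ground-truth synthetic-experiment generator that makes every stage of the
analysis verifiable by parameter recovery.

## The scientific problem

Cochlear IHCs release glutamate onto type-I spiral ganglion neurons in a
graded, voltage-dependent way, and the ~12 ribbon-type active zones (AZs)
of one IHC differ systematically in threshold, dynamic range and
Ca²⁺-coupling — a candidate substrate for the diversity of auditory-nerve
fibers. Probing this requires reducing two-channel movies (iGluSnFR
glutamate reporter on postsynaptic boutons at 50 Hz; Rhod-FF Ca²⁺ indicator
imaged at 100 Hz across 5 planes) plus simultaneous voltage-clamp traces to
a handful of per-synapse transfer parameters:

* **Ca²⁺ influx**: the ramp-evoked fluorescence–voltage relation is fitted
  with a driving-force-modified Boltzmann,
  `F(V) = F₀ + g_max·(V − V_r) / (1 + exp((V₁/₂ − V)/k))`, with the
  reversal potential fixed at V_r = +47.6 mV;
* **release**: normalized iGluSnFR-AUC versus step potential is fitted with
  a Boltzmann `1 / (1 + exp((V₁/₂ − V)/k))`; threshold V₁₀ = V₁/₂ − k·ln 9
  and 10–90% dynamic range k·ln 81 follow in closed form;
* **coupling**: the apparent Ca²⁺ cooperativity `m` is the exponent of a
  power fit `release = A·(Ca signal)^m` over −57…−17 mV, restricted to
  release below 25% of maximum (m ≲ 2: nanodomain-like control; m ≫ 2:
  microdomain-like);
* **pool dynamics**: cumulative release versus stimulus duration is fitted
  with `RRP·(1 − e^(−t/τ)) + slope·t`; rates convert to vesicles via
  40 aF/vesicle, 12 AZs/cell and 0.23 a.u. of iGluSnFR-AUC per vesicle;
* **position**: each synapse gets a coordinate on the pillar–modiolar axis
  (major axis of an ellipse fitted to the cell's baseline fluorescence),
  and the population table is phenotyped with K-means (K = 3 on 11
  z-scored properties, clusters ordered by ascending m) and PCA.

Because the original raw recordings are not publicly available, the package
ships a first-class synthetic module (`ihcsynapse.synthgen`) that renders
complete experiments — movies with Gaussian AZ hot spots inside an
elliptical cell, out-of-focus attenuation, photobleaching, a 33.3 Hz
spinning-disk artifact, shot/read noise, and matching ephys traces — from
known per-synapse parameters, so the whole pipeline is testable end to end.

## Worked example

`examples/03_fit_transfer_functions.py` generates one synapse, renders its
ramp and step responses at default noise, and fits everything back:

```
Ca2+ FV fit:  V1/2 -41.74 mV (true -41.52), k 4.84 mV (true 4.31), R^2 0.998
  descriptors: threshold V10 -52.38 mV, dynamic range 21.26 mV
release fit:  V1/2 -41.72 mV, k 2.38 mV, V10 -46.95 mV, dynamic range 10.46 mV, R^2 0.989
cooperativity m = 2.61 (apparent truth 2.20, rate-law m 2.98), R^2 1.000
```

The Ca²⁺ half-activation voltage is recovered to a fraction of a mV; the
release curve is steeper than the Ca²⁺ curve (k 2.4 vs 4.8 mV) because
release is supralinear in Ca²⁺; and the fitted m quantifies exactly that
supralinearity. The "apparent truth" is the same estimator applied to the
noiseless closed-form responses — readily-releasable-pool depletion
compresses the measured release–Ca²⁺ relation below the rate-law exponent
(see `docs/methods.md`).

The other examples cover generation and I/O (`01`), segmentation and
ΔF/F₀ trace reduction (`02`), pool dynamics and vesicle-unit conversions
(`04`, printing the 504 and ~185 SV/s-per-AZ conversions), and the
multi-cell population pipeline with clustering and the pillar–modiolar
gradient (`05`). A thin CLI wraps the same calls:

```bash
ihcsynapse generate --n-synapses 2 --seed 7 --out exp.h5
ihcsynapse run --preset paper --seed 1 --out-dir runs/paper
```

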