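# abrffr

Analysis pipeline for studying **age-related cochlear synaptopathy** with
auditory evoked potentials: auditory brainstem response (ABR) wave I/V
measurement with detection-floor censoring, frequency-following response
(FFR) envelope/fine-structure spectral SNR estimation, group-delay latency
estimation, and Bayesian robust mixed-effects inference — exercised end to
end on synthetic EEG-like recordings with known ground truth.

## Who it is for

Auditory-neuroscience and hearing-science groups running ABR/FFR
paradigms in which the quantities of interest are *small effects near the
measurement floor*: wave I amplitudes of tens of nanovolts, spectral
components a few dB above the noise, latencies inferred from phase
slopes. The package provides both the signal-processing chain and the
statistics, plus a simulator so every stage can be validated against
known truth before any real data are touched.

## What it computes

**Stimulus design.** Clicks bandpass filtered to 0.35–3 kHz presented at
a combined binaural rate of 14.1/s (7.05/s per ear, 50.9 ms silent
interval), optionally embedded in a highpass pink-noise masker; dual AM
tones (carriers 0.6/2 kHz, modulation frequencies 93.3–120 Hz) embedded
in notched pink noise, with notch edges one ERB-number either side of
each carrier on the Cam scale (Cam(f) = 21.4·log₁₀(0.00437f + 1)): the
default carriers give the noise bands 20–515, 694–1773, 2253–3000 Hz.
An AM tone of depth *m* over a carrier at level *L* has overall level
*L* + 10·log₁₀(1 + *m*²/2): 76.76 dB SPL at 100% depth, 75.95 dB at 70%,
for a 75 dB SPL carrier.

**ABR measurement.** Zero-phase FIR bandpass (0.1–1.5 kHz, 256 taps),
epoching (−3 to 12 ms) with 3-ms baseline, iterative-weighted averaging
(blocks weighted by inverse residual-noise variance), ear averaging, and
automatic peak picking: wave amplitude is peak minus following trough
(nV), latency the parabolically refined peak time. Undetected waves are
*censored*: coded as lying below the lowest detected amplitude in the
dataset and handled by integrating the likelihood below that bound.

**FFR measurement.** Epochs of −5 to 450 ms are averaged per polarity;
the polarity *sum* isolates envelope (ENV) components and the *difference*
isolates temporal-fine-structure (TFS) components. Component SNR is the
power at the FFT bin nearest the target over the mean per-bin power of 12
flanking bins (offsets ±3…±8; adjacent bins excluded for leakage). Only
components with SNR > 6.64 dB (the 1% point of the corresponding
F₂,₂ₘ test, m = 12) enter latency estimation, and a latency is attempted
only when all four modulation frequencies pass.

**Group delay.** For four components at closely spaced frequencies, every
phase unwrapping consistent with latencies in 0–30 ms is enumerated, each
candidate fit by least squares of phase vs frequency, and the best fit
kept; latency is −slope/2π, accepted only when the phase-residual MSE is
below 0.01 rad². An independent brute-force oracle (grid scan of the
circular residual sum) verifies the fitter.

**Inference.** y_ij = x_ij′β + b_i + ε_ij with subject intercepts
b_i ~ N(0, σ_u²) and Student-t residuals (ν free, > 2); censored
amplitude rows contribute the t-CDF at the log bound. Subject intercepts
are marginalized by Gauss–Hermite quadrature and the posterior sampled
with an affine-invariant ensemble sampler; effects are summarized by
posterior medians and 99% credibility intervals, with log-amplitude age
slopes reported as percent change per age decade, 100·(e^{10β} − 1).
A robust bivariate Student-t model gives Bayesian correlations among
cohort covariates (age, pure-tone averages, log₁₀ cumulative noise
exposure, cube-root years of musical experience).

## Worked example

```sh
abrffr simulate --out demo --seed 7   # 20-subject synthetic cohort
abrffr abr      --out demo            # measure wave I/V
abrffr fit      --out demo            # censored robust mixed model
abrffr report   --out demo
```

prints

```
simulated 20 subjects into demo
measured 80 waves (0 censored) -> demo/abr_measurements.csv
wave I age effect: -21.0% per decade (99% CI -31.4 to -9.4)
Age effects (wave I amplitude):
  -21.0% per decade (99% CI -31.4 to -9.4)
  simulated truth -17.0% per decade (inside the interval)
```

The simulator embedded a wave I amplitude declining 17% per age decade;
the measurement + inference chain recovers a posterior median of −21.0%
with the truth well inside the 99% credibility interval — the kind of
round trip every stage of the pipeline is tested with. The run directory
contains the cohort table, per-wave measurements with censoring flags,
posterior summaries and convergence diagnostics, all keyed to the
configuration hash that produced them.

The same stages are available as library functions (`abrffr.pipeline`,
`abrffr.inference`, `abrffr.synth`) for scripted studies.

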