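# Methods

This note documents the models, conventions and numerical choices behind
`abrffr`, in the spirit of a statistical methods appendix: what is
computed, under which assumptions, and where the genuinely open design
choices were made.

## Stimulus arithmetic

AM-tone levels follow from sideband power: modulating a carrier of level
L with depth m multiplies total power by 1 + m²/2, so
L_total = L + 10·log₁₀(1 + m²/2). Notch edges around a carrier use the
Glasberg–Moore auditory-filter scale, Cam(f) = 21.4·log₁₀(0.00437f + 1),
with edges at Cam(cf) ± 1 and rounding half-away-from-zero to 1 Hz; this
placement reproduces all four canonical edges (515, 694, 1773, 2253 Hz)
for the 0.6/2-kHz carriers. Presentation schedules conserve time exactly:
burst + silent interval = 1/rate, per-ear rate is half the combined rate
under strict alternation, and the click onset is jittered uniformly in
(5, 13) ms inside the masker burst. The click realization is a 100-µs
rectangular pulse through a windowed-sinc bandpass (0.35–3 kHz, 1025 taps
at 48 kHz — the order is a module constant chosen for >50 dB stopband
rejection; only the corner frequencies are physically prescribed), with
the 2-ms segment centered on the filtered peak. Pink noise is synthesized
by frequency-domain shaping (−3 dB/octave amplitude within band, zero
outside and inside notches) of seeded white Gaussian noise. Sound levels
are metadata: no transducer model is implemented, and synthesized
waveforms are calibrated relative to a unit-RMS reference.

## Preprocessing

Zero-phase filtering is a single forward pass of a linear-phase FIR with
its exact (N−1)/2-sample delay removed (even tap counts are bumped by
one); this matches a "zero-phase-shift FIR" contract without the squared
magnitude response of forward–backward filtering. The taps are
mean-subtracted to place an exact null at DC (the windowed-sinc design
otherwise leaves ~38 dB attenuation at DC with 257 taps at 16.4 kHz; the
passband perturbation of the subtraction is negligible). Epoch windows
are half-open [t0, t1) in samples with the trigger sample at t = 0, and
baseline correction subtracts the per-epoch mean over a window that must
lie inside the epoch.

**Iterative-weighted averaging.** Epochs are grouped into consecutive
blocks (default size 1); each block's noise variance is the temporal
variance of (block mean − current grand estimate), weights are inverse
variances normalized to 1, and the estimate is re-formed until its
relative RMS change falls below 1e-6 (max 50 passes). Zero-variance
blocks (noiseless data) share the weight uniformly. The residual-noise
variance of the average, Σ w² σ²_b, is carried forward and is what wave
detectability is judged against. Under *exactly* equal block variances
the weighted average equals the arithmetic mean identically; under iid
noise the sample variances differ, so equality holds only in
expectation — the equality test therefore uses orthogonal equal-norm
noise constructions. The blocking, tolerance and iteration cap are this
package's choices; only the inverse-variance principle is prescribed.

## ABR peak picking

Fully automatic (no human confirmation step): the peak is the largest
local maximum in the wave's search window (ties to the earlier latency),
the trough is the deepest point within a bounded window (default 4 ms)
after the peak — identical to the "first local minimum" on a clean
biphasic deflection but robust to one-sample noise dips — and amplitude
is peak minus trough. Latency is refined by parabolic interpolation
around the peak sample (sub-sample accuracy ≤ 1 sample by construction).
Search windows default to 1.0–3.5 ms (wave I) and 4.5–9.0 ms (wave V),
widened 0.5 ms at the lower click level; they are configuration, not
constants.

**Detectability.** A wave is detected when its amplitude exceeds 5.8×
the residual-noise SD of the average. The constant is the ~95th
percentile of the *noise-only* picked amplitude in noise-SD units
(measured by running the picker on pure noise in a wave-I-sized window),
so an absent wave is declared undetected about 95% of the time; a
fixed SNR-of-1 rule would detect noise nearly always, because the
picked peak-trough of pure noise is typically 3–5 SDs. The noise-floor
estimator runs the same picker on a pre-stimulus window of matching
duration and summarizes the "dummy wave" amplitudes by geometric
mean/SD, reporting the fraction of responses where no dummy wave was
measurable.

**Censoring.** Undetected amplitudes are coded as lying below the lowest
*detected* amplitude in the dataset (the empirical detection floor); the
measurement table carries the bound and a flag, and the inference layer
integrates the likelihood below the bound rather than dropping the rows.

## FFR spectral estimation

Addition/subtraction waveforms are (r ± c)/2 of the polarity averages;
the half keeps single-polarity component amplitudes unchanged (any
consistent scale would do — SNR is scale-free). The epoch is Hamming-
windowed and transformed without zero padding (455-ms epochs give
2.198-Hz bins). Signal power is read from the bin nearest the target;
noise power is the **mean per-bin power** of the 12 bins at offsets
±3…±8. The per-bin mean (not the raw 12-bin sum) is what makes a null
component's SNR sit near 0 dB; with the raw sum every SNR would be
offset by −10·log₁₀12 ≈ −10.8 dB.

*Null calibration convention.* Even with the per-bin mean, the
expectation depends on how "mean SNR" is taken: the mean of per-draw dB
values is ≈ −2.3 dB (Jensen), the dB of the mean per-draw power ratio is
≈ +0.6 dB (the Hamming window correlates neighboring bins, inflating
E[1/mean]), and the dB of (mean signal power)/(mean noise power) is
exactly 0. The calibration studies report the last — the power-domain
pooled mean — as the estimator's null level.

*Phases.* The phase entering group-delay estimation is evaluated by a
single-point DTFT at the **exact** target frequency on the epoch time
base (t = 0 at stimulus onset), not at the nearest bin: the window's
linear phase at a half-bin offset is ≈ 1.4 rad for these epoch lengths,
which would destroy the phase-vs-frequency fit, while bin-vs-exact makes
no practical difference to power. Referencing the time base to stimulus
onset keeps the pre-stimulus segment from masquerading as extra delay.

*A stimulus-design caveat.* The two simultaneous modulation frequencies
are 17.8 Hz apart — 8.1 bins — so the other carrier's ENV component falls
essentially on noise bin +8 of the 12-bin estimator. This is a property
of the paradigm, not of the estimator; it biases measured ENV SNRs
downward when components are strong. The estimator-calibration study
therefore injects a single isolated component (the generator supports
per-component amplitude overrides).

Components qualify for latency estimation only with SNR strictly greater
than 6.64 dB (the 1% criterion of an F test with 2 and 2m degrees of
freedom, m = 12, taken at its printed value), and only when all four
modulation frequencies' components for a target region pass. The CF+MF
envelope sideband is not analyzed; neither are the high carrier's TFS
components (above the phase-locking limit).

## Group-delay estimation

With the first component's phase fixed (the intercept absorbs a global
2π), every integer-2π adjustment of the remaining phases whose two-point
slope to the first component lies within the latency range (±π slack for
noise) is enumerated; each candidate is fit by OLS of unwrapped phase vs
frequency, latency = −slope/2π, and the minimum-MSE candidate wins, ties
broken toward the smaller latency. Acceptance requires latency in
0–30 ms and MSE < 0.01 rad² (phase residuals, radians²). The independent
oracle scans latency on a 0.01-ms grid minimizing Σ wrap(φᵢ + 2πfᵢτ − μ)²
with μ the circular mean; fitter and oracle agree to within twice the
grid step on random noiseless phase sets, which is the module's ground
truth for correctness. Estimates at the range edge are flagged.

Only ENV latencies propagate to inference; TFS latencies are too often
missing under the SNR rule to be analyzable, mirroring practice.

## Synthetic data

The generators are deliberately phenomenological — they produce data with
*known* embedded quantities, not biophysically realistic potentials:

* **Cohort.** Covariates (age, PTA 0.5–2, PTA 4–12, log₁₀ cumulative
  noise exposure, cube-root musical years) are drawn from a Gaussian
  copula. The latent correlation is calibrated per pair (Gauss–Hermite
  quadrature + root finding) so that the *output* Pearson correlations
  match the configured matrix despite non-Gaussian marginals; defaults
  are the strong age/high-frequency-threshold association (0.84),
  moderate age/low-frequency (0.37) and PTA/PTA (0.49) correlations, and
  near-zero elsewhere. Marginals: ages truncated-normal over 18–73
  (spanning young/middle/older bands), low-frequency PTA capped at the
  30.5 dB HL inclusion ceiling, noise exposure normal on the log scale
  spanning ~3 orders of magnitude, musical years gamma (right-skewed).
  Sex is drawn independently at the cohort's 27:7 female:male ratio.
* **ABR.** Each sweep embeds wave I and V as Gaussian-windowed biphasic
  deflections (widths 0.25/0.5 ms; nominal peaks 1.7/2.2 ms and
  5.6/6.5 ms at the high/low click level — plausible defaults, recorded
  in the exported ground truth, since no latency constants are
  prescribed anywhere). Log amplitude = linear age/sex/PTA/level
  predictor + subject intercept; ears alternate at 14.1/s. The manifest
  records the *realized* template peak (the biphasic maximum sits
  slightly before the Gaussian center).
* **FFR.** Polarity-balanced sweeps carry ENV components at both
  modulation frequencies (sign-invariant) and TFS components at CF−MF,
  CF, CF+MF of the low carrier (sign-inverting), each with phase
  −2πf·τ + φ₀ for configured group delay τ (default 14 ms, the typical
  scalp ENV latency regime).
* **Noise.** 1/f amplitude below a 100-Hz knee plus white noise, total
  RMS configured (default 1 µV — EEG-background order of magnitude).
  `noise_rms_for_component_snr` inverts the full measurement chain
  (sweep averaging, polarity combination, window gain at the sub-bin
  offset) to give the recording RMS that yields a target measured SNR.

What the generators do **not** emulate: cochlear nonlinearity, multiple
FFR sources with interfering latencies, wave latency dependence on age
or level beyond the configured constants, montage-specific source
projections (montage is at most a gain/noise factor), artifacts, or
non-stationary noise. Passing recovery tests therefore demonstrates the
*pipeline's* correctness on data satisfying the model assumptions, not
robustness to every property of real recordings.

## Inference

One observation model serves all outcome families:

    y_ij = x_ij'β + b_i + ε_ij,  b_i ~ N(0, σ_u²),  ε_ij ~ t_ν(0, σ_e)

with log-amplitude outcomes for ABR amplitudes (censoring bound log c)
and identity scales for latencies and SNRs. "Robust" is realized as
Student-t residuals with ν = 2 + exp(η) a free parameter, so outliers
are down-weighted continuously. Censored rows contribute
P(y < log c) = T_ν((log c − μ)/σ_e), which is what removes the upward
bias that dropping sub-floor amplitudes induces in age slopes.

Subject intercepts are marginalized by *adaptive* Gauss–Hermite
quadrature (11 nodes): for each subject the nodes are centered on the
conditional posterior mode of the intercept (Gaussian approximation from
the observed residuals) and scaled by the conditional SD, with the
importance ratio N(b; 0, σ_u²)/N(b; m_i, v_i) correcting the change of
measure. Plain quadrature on N(0, σ_u²) fails whenever σ_e ≪ σ_u — the
nodes straddle the narrow per-subject likelihood peak — which is exactly
the precise-measurement/large-between-subject-spread regime; the
adaptive rule matches brute-force numeric integration to ~1e-5 in log
likelihood on small fixtures. This leaves a (p+3)-dimensional
posterior sampled with the affine-invariant ensemble sampler using
differential-evolution moves (16 walkers, 2500 steps, 1000 burn-in,
thin 2 by default; all seeded). Priors are weakly informative on
standardized predictors: β ~ N(0, 10²), σ ~ half-normal(2), ν − 2
log-normal(1.5, 1). Continuous predictors are z-scored with scalers
stored for inversion; categorical predictors are dummy coded.

Diagnostics are rank-normalized split-R-hat and bulk ESS with walkers in
the role of chains. Interacting walkers read slightly high on R-hat
relative to independent chains, so the convergence flag uses 1.05
(together with ESS in the hundreds) rather than the 1.01 customary for
independent-chain samplers; summaries carry the raw values so stricter
screens can be applied downstream.

Derived effects are computed drawwise: percent change per age decade
100·(e^{10β} − 1) for log-scale slopes (β per year), slope differences
for level-ratio and modulation-depth contrasts, dB or ms per decade for
linear-scale outcomes. Covariate correlations use a robust bivariate
Student-t model per pair (medians + 99% CIs per pair is the required
output; a joint p-dimensional correlation model would add machinery
without changing any reported quantity); perfectly collinear pairs are
flagged degenerate.

With zero censored rows the censored and uncensored likelihoods are the
same code path, so their posteriors agree exactly under equal seeds — a
coherence property the tests assert.

## Problem sizes in the verification studies

The studies behind `scripts/acceptance.py` and the acceptance tests use:
1000 random phase sets (oracle agreement), 10⁴ Monte-Carlo draws (SNR
null), 20 replicate cohorts of 100 subjects with 2 measurements each
(censored recovery; ~30% censoring arises from placing mean amplitudes
near the detection floor), 100 repetitions of 20 heteroscedastic epochs
(averaging efficiency), and a 20-subject cohort at 100 sweeps/condition
(end-to-end). These sizes give Monte-Carlo error comfortably inside the
asserted tolerances while keeping a full verification run in the
ten-minute range; they are scale parameters, not statistical choices —
every study accepts larger values.

## Known limitations

* Single-source latency model: interfering FFR sources with different
  delays are out of scope by design.
* The ensemble sampler is run single-process; very large models (many
  interaction terms) would warrant a gradient-based sampler.
* Automatic peak picking has no human-confirmation loop; on real data
  the detectability constant should be re-calibrated against the
  recording montage and filter settings (the null percentile procedure
  in the ABR module docstring is the recipe).
* EDF reading requires the optional `mne` dependency; BDF export is not
  implemented — the native container is `.npz` with a JSON header.
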