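"""Synthetic cohorts and EEG-like recordings with known ground truth.

Every downstream stage (filtering, averaging, peak picking, spectral SNR,
group delay, censored inference) is exercised against data generated here,
where the embedded wave amplitudes, component phases and regression
coefficients are known exactly.

The generative models are deliberately simple rather than biophysical:

* ABR epochs carry wave I and wave V as Gaussian-windowed biphasic
  deflections whose log amplitude follows a linear age/sex/PTA model with
  a subject random intercept;
* FFR epochs carry steady-state envelope components (polarity-invariant)
  at the two modulation frequencies and fine-structure components
  (polarity-inverting) at CF-MF, CF, CF+MF of the low carrier, with
  phases -2*pi*f*tau + phi0 for a configured group delay tau;
* background noise is 1/f below a knee frequency plus white noise;
* covariates are drawn from a Gaussian copula whose latent correlation is
  calibrated so the *output* Pearson correlations match the configured
  matrix (defaults follow the observed cohort structure: age strongly
  correlated with high-frequency thresholds, moderately with
  low-frequency thresholds, essentially uncorrelated with noise exposure
  and musical experience).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .preprocess import Recording

__all__ = [
    "COVARIATES",
    "DEFAULT_CORRELATIONS",
    "GroundTruth",
    "SyntheticRecording",
    "sample_cohort",
    "simulate_abr_recording",
    "simulate_ffr_recording",
    "simulate_amplitude_table",
    "background_noise",
]

#: Continuous covariates in the default cohort model, in matrix order.
COVARIATES = ("age", "pta_0p5_2", "pta_4_12", "log10_tcne", "mus")

#: Default target Pearson correlations among the covariates.
DEFAULT_CORRELATIONS = np.array(
    [
        #  age   pta052 pta412 tcne   mus
        [1.00, 0.37, 0.84, 0.02, 0.10],
        [0.37, 1.00, 0.49, -0.11, -0.03],
        [0.84, 0.49, 1.00, 0.06, -0.06],
        [0.02, -0.11, 0.06, 1.00, -0.01],
        [0.10, -0.03, -0.06, -0.01, 1.00],
    ]
)

#: Marginal distributions (scipy frozen) for each covariate. Ages span
#: 18-73 covering the young/middle-aged/older bands; low-frequency
#: thresholds are bounded at the 30.5 dB HL inclusion ceiling.
_MARGINALS = {
    "age": stats.truncnorm((18 - 46) / 17, (73 - 46) / 17, loc=46, scale=17),
    "pta_0p5_2": stats.truncnorm(
        (-5 - 8) / 7, (30.5 - 8) / 7, loc=8, scale=7
    ),
    "pta_4_12": stats.truncnorm((-5 - 18) / 14, (70 - 18) / 14, loc=18, scale=14),
    "log10_tcne": stats.norm(loc=1.0, scale=0.9),
    # musical experience in cube-root years; years ~ gamma
    "mus": None,  # handled via the years marginal below
}
_YEARS_MARGINAL = stats.gamma(a=1.2, scale=6.0)

#: Proportion of females (27 of 34 per age group in the emulated cohort).
FEMALE_PROPORTION = 27.0 / 34.0


def _marginal_ppf(name: str, u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 1e-12, 1 - 1e-12)  # guard ppf at the copula tails
    if name == "mus":
        return np.cbrt(_YEARS_MARGINAL.ppf(u))
    return _MARGINALS[name].ppf(u)


def _transformed_moments(name: str, nodes: np.ndarray) -> tuple[float, float]:
    """Mean and SD of the transformed marginal at standard-normal nodes."""
    g = _marginal_ppf(name, stats.norm.cdf(nodes))
    return g


def _calibrate_latent_corr(
    name_i: str, name_j: str, target: float, n_gh: int = 48
) -> float:
    """Latent normal correlation giving the target output Pearson r.

    Uses Gauss-Hermite quadrature of E[g_i(Z1) g_j(Z2)] under a bivariate
    normal with correlation rho, solved for rho by bisection. Monotone in
    rho, so brentq is safe.
    """
    if abs(target) < 1e-12:
        return 0.0
    x, w = np.polynomial.hermite_e.hermegauss(n_gh)
    wi = w / np.sqrt(2 * np.pi)
    gi = _transformed_moments(name_i, x)
    gj = _transformed_moments(name_j, x)
    mi, si = wi @ gi, np.sqrt(wi @ gi**2 - (wi @ gi) ** 2)
    mj, sj = wi @ gj, np.sqrt(wi @ gj**2 - (wi @ gj) ** 2)

    def out_corr(rho: float) -> float:
        # E[gi(Z1) gj(Z2)], Z2 | Z1 ~ N(rho z1, 1-rho^2)
        s = np.sqrt(max(1e-12, 1.0 - rho**2))
        z2 = rho * x[:, None] + s * x[None, :]
        gj2 = _marginal_ppf(name_j, stats.norm.cdf(z2))
        inner = gj2 @ wi
        e = wi @ (gi * inner)
        return (e - mi * mj) / (si * sj)

    lo, hi = (-0.999, 0.0) if target < 0 else (0.0, 0.999)
    try:
        return float(
            optimize.brentq(lambda r: out_corr(r) - target, lo, hi, xtol=1e-4)
        )
    except ValueError:
        # target stronger than the copula can reach: saturate
        return hi if target > 0 else lo


def _nearest_pd(corr: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(corr)
    if vals.min() > 1e-8:
        return corr
    vals = np.clip(vals, 1e-8, None)
    m = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(m))
    return m / np.outer(d, d)


def sample_cohort(
    n: int,
    correlation: np.ndarray | None = None,
    seed: int = 0,
    *,
    calibrate: bool = True,
) -> pd.DataFrame:
    """Draw ``n`` subject covariate profiles from the Gaussian copula.

    ``correlation`` is the target Pearson matrix over
    (age, pta_0p5_2, pta_4_12, log10_tcne, mus); defaults to
    :data:`DEFAULT_CORRELATIONS`. When ``calibrate`` is true the latent
    correlation is adjusted per pair so the output correlations converge
    to the target despite the non-Gaussian marginals. pta_1_2 is derived
    from pta_0p5_2 with small jitter (its correlations are nearly
    identical). Sex is sampled independently with the cohort's
    female-majority proportion.
    """
    if n < 2:
        raise ValueError("need at least 2 subjects")
    target = DEFAULT_CORRELATIONS if correlation is None else np.asarray(
        correlation, dtype=float
    )
    if target.shape != (len(COVARIATES),) * 2:
        raise ValueError(f"correlation must be {len(COVARIATES)}x{len(COVARIATES)}")
    if np.linalg.eigvalsh(target).min() <= 0:
        raise ValueError("correlation matrix must be positive definite")
    latent = target.copy()
    if calibrate:
        for i in range(len(COVARIATES)):
            for j in range(i + 1, len(COVARIATES)):
                latent[i, j] = latent[j, i] = _calibrate_latent_corr(
                    COVARIATES[i], COVARIATES[j], target[i, j]
                )
    latent = _nearest_pd(latent)
    rng = np.random.default_rng(seed)
    z = rng.multivariate_normal(
        np.zeros(len(COVARIATES)), latent, size=n, method="cholesky"
    )
    u = stats.norm.cdf(z)
    cols = {
        name: _marginal_ppf(name, u[:, k]) for k, name in enumerate(COVARIATES)
    }
    df = pd.DataFrame(cols)
    df.insert(0, "subject", [f"S{i:04d}" for i in range(n)])
    df["sex"] = np.where(
        rng.random(n) < FEMALE_PROPORTION, "F", "M"
    )
    df["pta_1_2"] = df["pta_0p5_2"] + rng.normal(0, 1.0, n)
    df["age_group"] = pd.cut(
        df["age"], [0, 39.5, 59.5, np.inf],
        labels=["young", "middle", "older"],
    )
    return df


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Generative parameters exported alongside every simulated dataset.

    Amplitude effects are on the natural-log scale: ``age_slope_log`` is
    per *year* (so -17 %/decade corresponds to ln(0.83)/10 per year).
    """

    # ABR wave model (log-nV scale)
    wave_amp_nv: dict = field(
        default_factory=lambda: {"I": 150.0, "V": 400.0}
    )
    wave_latency_ms: dict = field(
        default_factory=lambda: {
            ("I", 105): 1.7, ("I", 80): 2.2,
            ("V", 105): 5.6, ("V", 80): 6.5,
        }
    )
    age_slope_log: float = float(np.log(0.83) / 10.0)  # per year
    sex_effect_log: float = -0.15  # male offset
    pta_slope_log: float = -0.01  # per dB HL
    level_effect_log: float = 0.5  # 105 vs 80 dB ppeSPL
    subject_sd_log: float = 0.35
    resid_sd_log: float = 0.25
    resid_df: float = 8.0
    reference_age: float = 46.0
    detection_floor_nv: float = 0.38

    # FFR model
    tau_ms: float = 14.0
    env_amp_nv: float = 40.0
    tfs_amp_nv: float = 25.0
    phi0: float = 0.8

    # background noise
    noise_rms_v: float = 1.0e-6
    noise_knee_hz: float = 100.0
    noise_pink_fraction: float = 0.5

    def to_json(self, path) -> None:
        d = asdict(self)
        d["wave_latency_ms"] = {
            f"{w}@{lv}": v for (w, lv), v in self.wave_latency_ms.items()
        }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2, default=float)

    def log_amplitude(
        self, wave: str, level: int, age: float, sex: str, pta: float,
        subject_effect: float = 0.0,
    ) -> float:
        """Linear predictor of log wave amplitude (nV)."""
        lp = (
            np.log(self.wave_amp_nv[wave])
            + self.age_slope_log * (age - self.reference_age)
            + (self.sex_effect_log if sex == "M" else 0.0)
            + self.pta_slope_log * pta
            + (self.level_effect_log if level == 105 else 0.0)
            + subject_effect
        )
        return float(lp)


@dataclass
class SyntheticRecording:
    """A continuous recording plus the manifest of what was embedded."""

    recording: Recording
    manifest: dict


# ---------------------------------------------------------------------------
# noise and wave shapes
# ---------------------------------------------------------------------------


def background_noise(
    n_samples: int,
    sampling_rate: float,
    rms: float,
    seed: int,
    *,
    knee_hz: float = 100.0,
    pink_fraction: float = 0.5,
) -> np.ndarray:
    """1/f-below-knee plus white background noise of total RMS ``rms``."""
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n_samples)
    freqs = np.fft.rfftfreq(n_samples, 1.0 / sampling_rate)
    shape = np.zeros_like(freqs)
    nz = freqs > 0
    shape[nz] = np.sqrt(knee_hz / np.maximum(freqs[nz], 1e-9))
    shape[freqs >= knee_hz] = np.minimum(shape[freqs >= knee_hz], 1.0)
    spec = shape * (
        rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)
    )
    spec[0] = 0.0
    pink = np.fft.irfft(spec, n_samples)
    pink_rms = np.sqrt(np.mean(pink**2))
    if pink_rms > 0:
        pink /= pink_rms
    x = pink_fraction * pink + (1 - pink_fraction) * white
    x_rms = np.sqrt(np.mean(x**2))
    return rms * x / x_rms if x_rms > 0 else x


def biphasic_wave(
    times_s: np.ndarray,
    peak_latency_s: float,
    width_s: float,
    amplitude_v: float,
) -> np.ndarray:
    """Gaussian-windowed biphasic deflection with unit peak-trough scale.

    A positive Gaussian at the peak latency followed by a negative one a
    little over one width later; the pair is normalized so its
    max-minus-min equals ``amplitude_v``.
    """
    sep = 1.2 * width_s
    g1 = np.exp(-0.5 * ((times_s - peak_latency_s) / width_s) ** 2)
    g2 = np.exp(-0.5 * ((times_s - peak_latency_s - sep) / width_s) ** 2)
    shape = g1 - 0.9 * g2
    span = shape.max() - shape.min()
    return amplitude_v * shape / span


#: Gaussian widths (s) of the simulated deflections per wave.
WAVE_WIDTHS_S = {"I": 0.25e-3, "V": 0.5e-3}


def simulate_abr_recording(
    subject: pd.Series | dict,
    condition: dict,
    truth: GroundTruth,
    n_sweeps: int = 10000,
    seed: int = 0,
    *,
    sampling_rate: float = 16384.0,
    combined_rate: float = 14.1,
    subject_effect: float | None = None,
    montage: str = "HF-ITPR",
) -> SyntheticRecording:
    """Continuous click-run recording for one subject and condition.

    ``condition`` needs ``level`` (80 or 105 dB ppeSPL) and ``masking``
    ("quiet" or "hp"). Triggers alternate ears at ``combined_rate``; each
    sweep embeds wave I and wave V deflections at the truth latencies with
    amplitude exp(linear predictor + subject effect) in nV, on top of
    1/f-plus-white background noise. The manifest records the embedded
    per-wave amplitudes and latencies.
    """
    if n_sweeps < 1:
        raise ValueError("n_sweeps must be >= 1")
    level = condition["level"]
    masking = condition.get("masking", "quiet")
    if masking not in ("quiet", "hp"):
        raise ValueError(f"unknown masking condition {masking!r}")
    if level not in (80, 105):
        raise ValueError(f"unknown click level {level!r}")
    rng = np.random.default_rng(seed)
    if subject_effect is None:
        subject_effect = rng.normal(0, truth.subject_sd_log)
    sub = dict(subject)
    amps_nv = {
        w: float(
            np.exp(
                truth.log_amplitude(
                    w, level, sub["age"], sub["sex"],
                    sub.get("pta_0p5_2", 0.0), subject_effect,
                )
            )
        )
        for w in ("I", "V")
    }
    period = 1.0 / combined_rate
    n_samples = int(round((n_sweeps + 1) * period * sampling_rate))
    x = (
        background_noise(
            n_samples, sampling_rate, truth.noise_rms_v, seed + 1,
            knee_hz=truth.noise_knee_hz,
            pink_fraction=truth.noise_pink_fraction,
        )
        if truth.noise_rms_v > 0
        else np.zeros(n_samples)
    )
    epoch_len = int(round(0.015 * sampling_rate))
    tloc = np.arange(epoch_len) / sampling_rate
    wave_templates = {
        w: biphasic_wave(
            tloc,
            truth.wave_latency_ms[(w, level)] * 1e-3,
            WAVE_WIDTHS_S[w],
            amps_nv[w] * 1e-9,
        )
        for w in ("I", "V")
    }
    # realized peak latency: the biphasic shape's maximum sits slightly
    # before the nominal Gaussian center
    peak_latency_ms = {
        w: float(tloc[int(np.argmax(tmpl))] * 1e3)
        for w, tmpl in wave_templates.items()
    }
    template = sum(wave_templates.values())
    triggers = []
    for k in range(n_sweeps):
        t = (k + 0.5) * period
        ear = "L" if k % 2 == 0 else "R"
        i = int(round(t * sampling_rate))
        x[i : i + epoch_len] += template
        triggers.append((t, f"click/{ear}/{level}/{masking}"))
    rec = Recording(
        channels={montage: x},
        sampling_rate=sampling_rate,
        triggers=triggers,
        meta={"subject": sub.get("subject"), "condition": condition},
    )
    manifest = {
        "amplitudes_nv": amps_nv,
        "latencies_ms": peak_latency_ms,
        "nominal_latencies_ms": {
            w: truth.wave_latency_ms[(w, level)] for w in ("I", "V")
        },
        "subject_effect": subject_effect,
        "noise_rms_v": truth.noise_rms_v,
    }
    return SyntheticRecording(rec, manifest)


def simulate_ffr_recording(
    subject: pd.Series | dict,
    stimulus_config: dict,
    truth: GroundTruth,
    n_sweeps: int = 1000,
    seed: int = 0,
    *,
    sampling_rate: float = 16384.0,
    montage: str = "HF-C7",
) -> SyntheticRecording:
    """Continuous AM-tone-run recording with balanced polarities.

    ``stimulus_config`` needs ``low_mf`` and ``high_mf`` (Hz) and
    optionally ``low_cf``/``high_cf`` (default 600/2000) and ``md``.
    Envelope components at both modulation frequencies keep their sign
    across polarity; fine-structure components at CF-MF, CF, CF+MF of the
    low carrier invert with polarity. Each component's phase is
    -2*pi*f*tau + phi0 for the configured group delay.
    """
    if n_sweeps % 2:
        raise ValueError("n_sweeps must be even to balance polarities")
    low_cf = stimulus_config.get("low_cf", 600.0)
    high_cf = stimulus_config.get("high_cf", 2000.0)
    low_mf = stimulus_config["low_mf"]
    high_mf = stimulus_config["high_mf"]
    md = stimulus_config.get("md", 1.0)
    tau = truth.tau_ms * 1e-3
    epoch_dur = 0.455
    period = 0.500
    n_samples = int(round((n_sweeps + 1) * period * sampling_rate))
    x = (
        background_noise(
            n_samples, sampling_rate, truth.noise_rms_v, seed + 1,
            knee_hz=truth.noise_knee_hz,
            pink_fraction=truth.noise_pink_fraction,
        )
        if truth.noise_rms_v > 0
        else np.zeros(n_samples)
    )
    epoch_len = int(round(epoch_dur * sampling_rate))
    tloc = np.arange(epoch_len) / sampling_rate

    # per-component amplitude overrides (nV), e.g. to simulate a single
    # isolated component for estimator calibration
    low_env = stimulus_config.get("low_env_amp_nv", truth.env_amp_nv) * md
    high_env = stimulus_config.get("high_env_amp_nv", truth.env_amp_nv) * md
    tfs_amp_nv = stimulus_config.get("tfs_amp_nv", truth.tfs_amp_nv)
    env_amps = {low_mf: low_env * 1e-9, high_mf: high_env * 1e-9}
    tfs_freqs = [low_cf - low_mf, low_cf, low_cf + low_mf]
    mk = lambda f, a: a * np.cos(
        2 * np.pi * f * tloc + (-2 * np.pi * f * tau + truth.phi0)
    )
    env_sig = sum(mk(f, a) for f, a in env_amps.items())
    tfs_sig = sum(mk(f, tfs_amp_nv * 1e-9) for f in tfs_freqs)

    triggers = []
    for k in range(n_sweeps):
        t = (k + 0.05) * period
        pol = "rarefaction" if k % 2 == 0 else "condensation"
        sgn = 1.0 if pol == "rarefaction" else -1.0
        i = int(round(t * sampling_rate))
        x[i : i + epoch_len] += env_sig + sgn * tfs_sig
        triggers.append((t, f"am/{pol}/md{md:g}"))
    rec = Recording(
        channels={montage: x},
        sampling_rate=sampling_rate,
        triggers=triggers,
        meta={"subject": dict(subject).get("subject"),
              "stimulus_config": stimulus_config},
    )
    manifest = {
        "tau_ms": truth.tau_ms,
        "phi0": truth.phi0,
        "env": dict(env_amps),
        "tfs": {f: tfs_amp_nv * 1e-9 for f in tfs_freqs},
        "noise_rms_v": truth.noise_rms_v,
    }
    return SyntheticRecording(rec, manifest)


def noise_rms_for_component_snr(
    target_snr_db: float,
    amp_v: float,
    target_freq: float,
    n_sweeps: int,
    sampling_rate: float,
    window_s: tuple[float, float] = (-0.005, 0.450),
) -> float:
    """White-noise recording RMS giving an expected component SNR.

    Works backwards through the measurement chain: averaging ``n_sweeps``
    epochs (half per polarity) and halving the polarity sum leaves noise
    variance ``rms^2 / n_sweeps`` per sample; the Hamming-windowed FFT
    then sees expected per-bin noise power ``var * sum(w^2)`` while the
    component of amplitude ``amp_v`` lands ``(amp/2)^2 |W(df)|^2`` in its
    nearest bin, with ``W`` the window transform at the sub-bin offset.
    Solving the ratio for ``rms`` calibrates the injected noise so the
    measured SNR converges to ``target_snr_db``.
    """
    fs = sampling_rate
    i0 = int(round(window_s[0] * fs))
    i1 = int(round(window_s[1] * fs))
    n = i1 - i0
    w = np.hamming(n)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    k = int(np.argmin(np.abs(freqs - target_freq)))
    # window transform gain at the sub-bin offset
    t = np.arange(n) / fs
    gain = np.abs(np.sum(w * np.exp(2j * np.pi * (freqs[k] - target_freq) * t)))
    sig_power = (amp_v / 2.0) ** 2 * gain**2
    per_bin_per_var = np.sum(w**2)
    target = 10.0 ** (target_snr_db / 10.0)
    var_add = sig_power / (target * per_bin_per_var)
    return float(np.sqrt(var_add * n_sweeps))


def simulate_amplitude_table(
    cohort: pd.DataFrame,
    truth: GroundTruth,
    seed: int = 0,
    *,
    level: int = 105,
    masking: str = "quiet",
    wave: str = "I",
    n_replicates: int = 4,
    censor_bound_nv: float | None = None,
) -> pd.DataFrame:
    """Measurement-level amplitude table directly from the linear model.

    Bypasses waveform simulation: draws ``n_replicates`` log-amplitude
    observations per subject (subject random intercept + Student-t
    residual), then marks observations below the censoring bound
    (default: the truth's detection floor) as censored and sets their
    amplitude to the bound. Used for inference-recovery studies where the
    waveform pipeline would only add compute, not information.
    """
    rng = np.random.default_rng(seed)
    bound = (
        truth.detection_floor_nv if censor_bound_nv is None else censor_bound_nv
    )
    rows = []
    for _, sub in cohort.iterrows():
        b = rng.normal(0, truth.subject_sd_log)
        for rep in range(n_replicates):
            lp = truth.log_amplitude(
                wave, level, sub["age"], sub["sex"], sub["pta_0p5_2"], b
            )
            y = lp + truth.resid_sd_log * rng.standard_t(truth.resid_df)
            amp = float(np.exp(y))
            censored = amp < bound
            rows.append(
                {
                    "subject": sub["subject"],
                    "age": sub["age"],
                    "sex": sub["sex"],
                    "pta_0p5_2": sub["pta_0p5_2"],
                    "wave": wave,
                    "level": level,
                    "masking": masking,
                    "replicate": rep,
                    "amplitude_nv": bound if censored else amp,
                    "censored": censored,
                    "censor_bound_nv": bound,
                }
            )
    return pd.DataFrame(rows)
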