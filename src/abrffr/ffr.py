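"""Envelope / fine-structure decomposition of frequency-following responses.

Averages to opposite stimulus polarities are summed to isolate envelope
(ENV) components — which are polarity-invariant because envelope coding is
a rectification product — and subtracted to isolate temporal-fine-structure
(TFS) components, which invert with stimulus polarity.

Component SNR uses the classic single-bin estimator: signal power at the
FFT bin nearest the target frequency, noise power as the mean per-bin power
of the 12 surrounding bins (six per side at offsets +/-3..+/-8; the two
bins immediately adjacent on each side are excluded to keep spectral
leakage out of the noise estimate). An SNR above 6.64 dB has < 1%
probability under the null hypothesis of equal signal and noise power
(F test with 2 and 2m degrees of freedom, m = 12 noise bins).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import AveragedResponse

__all__ = [
    "PolarityPair",
    "SpectralComponent",
    "SNR_INCLUSION_DB",
    "NOISE_BIN_OFFSETS",
    "add_sub",
    "component_snr",
    "extract_components",
    "apply_inclusion_criterion",
    "MODULATION_FREQS",
]

#: SNR criterion (dB) for including a component in group-delay estimation;
#: the comparison is strictly greater-than.
SNR_INCLUSION_DB = 6.64

#: Noise bins relative to the signal bin: six per side, skipping the two
#: adjacent bins on each side.
NOISE_BIN_OFFSETS = tuple(range(-8, -2)) + tuple(range(3, 9))

#: The four modulation frequencies (Hz) used across stimulus configurations.
MODULATION_FREQS = (93.3, 102.2, 111.1, 120.0)

#: CF/MF pairing per stimulus configuration: (low-carrier MF index,
#: high-carrier MF index), zero-based into MODULATION_FREQS.
STIMULUS_CONFIGS = {
    "LCF_MF1/HCF_MF3": (0, 2),
    "LCF_MF2/HCF_MF4": (1, 3),
    "LCF_MF3/HCF_MF1": (2, 0),
    "LCF_MF4/HCF_MF2": (3, 1),
}


@dataclass(frozen=True)
class PolarityPair:
    """Averaged responses to rarefaction and condensation polarities."""

    rarefaction: AveragedResponse
    condensation: AveragedResponse

    def __post_init__(self) -> None:
        if not np.allclose(self.rarefaction.times, self.condensation.times):
            raise ValueError("polarity averages must share a time base")


@dataclass(frozen=True)
class SpectralComponent:
    """One target frequency's signal/noise power, SNR and phase.

    ``freq`` is the requested target frequency; ``bin_freq`` the center of
    the FFT bin the signal power was read from. ``phase`` is evaluated by
    a single-point DTFT at the *exact* target frequency on the epoch time
    base (t=0 at stimulus onset): a nearest-bin phase would carry the
    window's linear-phase error of up to ~pi/2 for a half-bin offset,
    which is fatal for group-delay fitting, while power is insensitive to
    the sub-bin offset at the Hamming window's flatness.
    """

    freq: float
    signal_power: float
    noise_power: float  # per-bin mean over the 12 noise bins
    snr_db: float
    phase: float  # radians, principal branch (-pi, pi]
    kind: str  # "ENV" or "TFS"
    carrier: float | None = None
    mf: float | None = None
    bin_freq: float | None = None


def add_sub(pair: PolarityPair) -> tuple[AveragedResponse, AveragedResponse]:
    """Addition and subtraction waveforms of a polarity pair.

    addition = (rarefaction + condensation)/2 keeps ENV, cancels TFS;
    subtraction = (rarefaction - condensation)/2 keeps TFS, cancels ENV.
    The common factor of one half keeps single-polarity component
    amplitudes unchanged; any consistent scale would do as SNR is
    scale-invariant.
    """
    r, c = pair.rarefaction, pair.condensation
    mk = lambda w: AveragedResponse(
        waveform=w,
        times=r.times,
        weights=np.concatenate([r.weights, c.weights]) / 2.0,
        noise_variance=(r.noise_variance + c.noise_variance) / 4.0,
        n_epochs=r.n_epochs + c.n_epochs,
    )
    return (
        mk((r.waveform + c.waveform) / 2.0),
        mk((r.waveform - c.waveform) / 2.0),
    )


def component_snr(
    waveform: np.ndarray,
    sampling_rate: float,
    target_freq: float,
    *,
    t0: float = 0.0,
    kind: str = "ENV",
    carrier: float | None = None,
    mf: float | None = None,
    window: str = "hamming",
) -> SpectralComponent:
    """Single-bin spectral SNR of ``waveform`` at ``target_freq``.

    The waveform is Hamming-windowed and transformed without zero padding,
    so the bin spacing is sampling_rate / len(waveform). Noise power is
    the mean per-bin power over offsets +/-3..+/-8 from the signal bin.
    ``t0`` is the epoch time of the first sample (e.g. -0.005 s when the
    segment starts 5 ms before stimulus onset) so phases are referenced
    to stimulus onset, which group-delay estimation requires.
    """
    x = np.asarray(waveform, dtype=float)
    n = x.size
    if window == "hamming":
        w = np.hamming(n)
    elif window is None or window == "none":
        w = np.ones(n)
    else:
        raise ValueError(f"unknown window {window!r}")
    xw = x * w
    spec = np.fft.rfft(xw)
    power = np.abs(spec) ** 2
    freqs = np.fft.rfftfreq(n, 1.0 / sampling_rate)
    if target_freq > freqs[-1]:
        raise ValueError("target frequency above Nyquist")
    k = int(np.argmin(np.abs(freqs - target_freq)))
    noise_bins = np.array([k + o for o in NOISE_BIN_OFFSETS])
    if noise_bins.min() < 0 or noise_bins.max() >= power.size:
        raise ValueError(
            "fewer than 12 valid noise bins: target too close to the "
            "spectrum edge"
        )
    signal_power = float(power[k])
    noise_power = float(power[noise_bins].mean())
    snr_db = 10.0 * np.log10(signal_power / noise_power)
    # exact-frequency phase on the epoch time base
    t = t0 + np.arange(n) / sampling_rate
    phase = float(np.angle(np.sum(xw * np.exp(-2j * np.pi * target_freq * t))))
    return SpectralComponent(
        freq=float(target_freq),
        signal_power=signal_power,
        noise_power=noise_power,
        snr_db=float(snr_db),
        phase=phase,
        kind=kind,
        carrier=carrier,
        mf=mf,
        bin_freq=float(freqs[k]),
    )


def extract_components(
    addition: AveragedResponse,
    subtraction: AveragedResponse,
    config: str,
    *,
    low_carrier: float = 600.0,
    high_carrier: float = 2000.0,
) -> list[SpectralComponent]:
    """ENV and TFS components for one stimulus configuration.

    ENV components are taken from the addition waveform at both carriers'
    modulation frequencies. TFS components are taken from the subtraction
    waveform at CF-MF, CF and CF+MF of the *low* carrier only: the high
    carrier's fine structure is above the phase-locking limit and elicits
    no scalp-recordable response.
    """
    if config not in STIMULUS_CONFIGS:
        raise ValueError(
            f"unknown stimulus configuration {config!r}; "
            f"expected one of {sorted(STIMULUS_CONFIGS)}"
        )
    low_i, high_i = STIMULUS_CONFIGS[config]
    low_mf = MODULATION_FREQS[low_i]
    high_mf = MODULATION_FREQS[high_i]
    fs = addition.sampling_rate
    t0 = float(addition.times[0])
    comps = [
        component_snr(
            addition.waveform, fs, low_mf, t0=t0,
            kind="ENV", carrier=low_carrier, mf=low_mf,
        ),
        component_snr(
            addition.waveform, fs, high_mf, t0=t0,
            kind="ENV", carrier=high_carrier, mf=high_mf,
        ),
    ]
    for f in (low_carrier - low_mf, low_carrier, low_carrier + low_mf):
        comps.append(
            component_snr(
                subtraction.waveform, fs, f, t0=t0,
                kind="TFS", carrier=low_carrier, mf=low_mf,
            )
        )
    return comps


def apply_inclusion_criterion(
    components: list[SpectralComponent],
    threshold_db: float = SNR_INCLUSION_DB,
) -> list[SpectralComponent]:
    """Components whose SNR strictly exceeds the criterion.

    Group-delay estimation additionally requires all four modulation
    frequencies' components for a target frequency region to pass; that
    all-four rule is enforced by the caller that collates across stimulus
    configurations (see :func:`abrffr.groupdelay.fit_group_delay` users).
    """
    return [c for c in components if c.snr_db > threshold_db]


def all_passed(components: list[SpectralComponent],
               threshold_db: float = SNR_INCLUSION_DB) -> bool:
    """True when every one of the supplied components passes the criterion.

    Used to apply the all-four-MFs rule for a target frequency region.
    """
    return len(components) > 0 and all(
        c.snr_db > threshold_db for c in components
    )
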