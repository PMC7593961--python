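"""Acoustic stimulus specifications and waveform synthesis.

Two stimulus families are covered:

* transient: a 100-us click bandpass filtered to 0.35-3 kHz, optionally
  embedded in a 20-ms burst of highpass (3.5-8 kHz) pink noise that masks
  basal cochlear regions, presented with alternating ears at a combined
  rate of 14.1/s;
* sustained: two simultaneous sinusoidally amplitude-modulated (AM) tones
  (carriers 0.6 and 2 kHz, modulation frequencies near 100 Hz) embedded in
  pink noise with ERB-wide spectral notches around each carrier.

Levels are stored as metadata in dB SPL (or dB ppeSPL for transients);
no transducer model is applied, so synthesized waveforms are calibrated
relative to a unit-RMS = 0 dB convention documented per function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy import signal as sps

__all__ = [
    "ClickStimulus",
    "HighpassMasker",
    "AMTone",
    "NotchedNoise",
    "PresentationSchedule",
    "am_tone_level",
    "cam",
    "cam_inverse",
    "erb_notch_edges",
    "build_abr_schedule",
    "synthesize_am_tone",
    "synthesize_click",
    "synthesize_pink_noise",
    "synthesize_notched_noise",
    "synthesize_highpass_masker",
]

#: FIR order used to band-limit the click (windowed-sinc, Hamming). The
#: corner frequencies are fixed by the design; the order is a module
#: constant chosen for >50 dB stopband rejection at 48 kHz.
CLICK_FILTER_TAPS = 1025

#: Duration of the raw rectangular click pulse, seconds.
CLICK_PULSE_DURATION = 100e-6


@dataclass(frozen=True)
class ClickStimulus:
    """Bandpass-filtered click transient.

    The stimulus is the 2-ms portion of the filtered pulse centered on its
    peak; ``band`` gives the bandpass corner frequencies in Hz and ``level``
    the presentation level in dB peak-to-peak-equivalent SPL.
    """

    duration: float = 0.002
    band: tuple[float, float] = (350.0, 3000.0)
    level: float = 105.0


@dataclass(frozen=True)
class HighpassMasker:
    """Highpass pink-noise burst masking basal cochlear regions."""

    band: tuple[float, float] = (3500.0, 8000.0)
    spectrum_level: float = 65.0  # dB SPL at the 1-kHz reference
    reference_freq: float = 1000.0
    duration: float = 0.020
    ramp: float = 0.005
    color: str = "pink"


@dataclass(frozen=True)
class AMTone:
    """Sinusoidally amplitude-modulated tone.

    ``overall_level`` is derived from the carrier level and modulation
    depth: modulating a carrier of level L with depth m adds sideband
    power so the total level is L + 10*log10(1 + m^2/2).
    """

    carrier_freq: float
    mod_freq: float
    mod_depth: float = 1.0
    carrier_level: float = 75.0
    duration: float = 0.450
    ramp: float = 0.010

    @property
    def overall_level(self) -> float:
        return am_tone_level(self.carrier_level, self.mod_depth)


@dataclass(frozen=True)
class NotchedNoise:
    """Pink noise with ERB-wide notches around the stimulated carriers."""

    bands: tuple[tuple[float, float], ...]
    spectrum_level: float = 40.0  # dB SPL at the 100-Hz reference
    reference_freq: float = 100.0
    notch_half_width: float = 1.0  # ERB-numbers per side

    def __post_init__(self) -> None:
        flat = [e for b in self.bands for e in b]
        if any(b[1] <= b[0] for b in self.bands):
            raise ValueError("each noise band must satisfy low < high")
        if flat != sorted(flat):
            raise ValueError("noise bands must be disjoint and ordered")


@dataclass(frozen=True)
class PresentationSchedule:
    """Timing of transient presentations under ear alternation."""

    combined_rate: float
    per_ear_rate: float
    burst_duration: float
    silent_interval: float
    click_onset_jitter: tuple[float, float] = (0.005, 0.013)

    def to_dict(self) -> dict:
        return asdict(self)


def am_tone_level(carrier_level: float, mod_depth: float) -> float:
    """Overall level (dB SPL) of an AM tone from its carrier level.

    Sinusoidal modulation with depth ``m`` adds two sidebands of amplitude
    m/2 relative to the carrier, so total power is scaled by 1 + m^2/2:

        L_total = L_carrier + 10*log10(1 + m^2/2)

    The returned value is exact; round only for display.

    >>> round(am_tone_level(75, 1.0), 2)
    76.76
    """
    if not 0.0 <= mod_depth <= 1.0:
        raise ValueError(
            f"mod_depth must lie in [0, 1], got {mod_depth!r}"
        )
    return carrier_level + 10.0 * math.log10(1.0 + mod_depth**2 / 2.0)


def cam(freq_hz):
    """ERB-number (Cam) of a frequency in Hz, Glasberg & Moore scale.

    Cam(f) = 21.4 * log10(0.00437 f + 1) with f in Hz.
    """
    f = np.asarray(freq_hz, dtype=float)
    return 21.4 * np.log10(0.00437 * f + 1.0)


def cam_inverse(cam_number):
    """Frequency in Hz at a given ERB-number on the Cam scale."""
    c = np.asarray(cam_number, dtype=float)
    return (10.0 ** (c / 21.4) - 1.0) / 0.00437


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def erb_notch_edges(carrier_freq: float) -> tuple[int, int]:
    """Edges (Hz) of a notch one ERB-number wide on each side of a carrier.

    The lower/upper edges sit exactly one Cam below/above the carrier,
    rounded half-away-from-zero to the nearest Hz.

    >>> erb_notch_edges(600)
    (515, 694)
    >>> erb_notch_edges(2000)
    (1773, 2253)
    """
    if carrier_freq <= 0:
        raise ValueError("carrier_freq must be positive")
    c = float(cam(carrier_freq))
    lo = float(cam_inverse(c - 1.0))
    hi = float(cam_inverse(c + 1.0))
    return _round_half_away(lo), _round_half_away(hi)


def build_abr_schedule(
    combined_rate: float, burst_duration: float
) -> PresentationSchedule:
    """Presentation schedule for ear-alternated transients.

    The silent interval between masker bursts fills the remainder of the
    stimulus period: 1/combined_rate = burst_duration + silent_interval.
    Under strict left/right alternation each ear is stimulated at half the
    combined rate. The click onset within each burst is jittered uniformly
    in (5, 13) ms to decorrelate the masker-onset response from the
    click-locked average.
    """
    if combined_rate <= 0:
        raise ValueError("combined_rate must be positive")
    period = 1.0 / combined_rate
    if burst_duration > period:
        raise ValueError(
            f"burst_duration {burst_duration} s exceeds the stimulus "
            f"period {period:.4f} s at {combined_rate}/s"
        )
    return PresentationSchedule(
        combined_rate=combined_rate,
        per_ear_rate=combined_rate / 2.0,
        burst_duration=burst_duration,
        silent_interval=period - burst_duration,
    )


# ---------------------------------------------------------------------------
# waveform synthesis
# ---------------------------------------------------------------------------

def _check_rate(sampling_rate: float, highest_edge: float) -> None:
    if sampling_rate < 2.0 * highest_edge:
        raise ValueError(
            f"sampling_rate {sampling_rate} Hz undersamples content up to "
            f"{highest_edge} Hz (need >= {2 * highest_edge} Hz)"
        )


def _raised_cosine_ramps(x: np.ndarray, sampling_rate: float, ramp: float) -> np.ndarray:
    n_ramp = int(round(ramp * sampling_rate))
    if n_ramp == 0:
        return x
    r = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
    out = x.copy()
    out[:n_ramp] *= r
    out[-n_ramp:] *= r[::-1]
    return out


def synthesize_am_tone(
    spec: AMTone, sampling_rate: float, *, rms_ref: float = 1.0
) -> np.ndarray:
    """Realize an AM tone; the carrier alone has RMS ``rms_ref``.

    With the carrier pinned at ``rms_ref`` the synthesized RMS relates to
    the nominal level by exactly the ``am_tone_level`` formula, which the
    tests exploit: 20*log10(rms/rms_ref) = overall_level - carrier_level
    (ignoring the negligible ramp contribution).
    """
    _check_rate(sampling_rate, spec.carrier_freq + spec.mod_freq)
    n = int(round(spec.duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    carrier_amp = rms_ref * math.sqrt(2.0)
    x = (
        carrier_amp
        * (1.0 + spec.mod_depth * np.sin(2 * np.pi * spec.mod_freq * t))
        * np.sin(2 * np.pi * spec.carrier_freq * t)
    )
    return _raised_cosine_ramps(x, sampling_rate, spec.ramp)


def synthesize_click(
    spec: ClickStimulus, sampling_rate: float
) -> np.ndarray:
    """Bandpass-filtered click: 100-us pulse through a windowed-sinc FIR.

    Returns the ``spec.duration`` window of the filtered sequence centered
    on its absolute peak.
    """
    _check_rate(sampling_rate, spec.band[1])
    n_pulse = max(1, int(round(CLICK_PULSE_DURATION * sampling_rate)))
    taps = sps.firwin(
        CLICK_FILTER_TAPS, spec.band, fs=sampling_rate, pass_zero=False
    )
    pulse = np.ones(n_pulse)
    filtered = np.convolve(pulse, taps)
    peak = int(np.argmax(np.abs(filtered)))
    half = int(round(spec.duration * sampling_rate)) // 2
    lo = max(0, peak - half)
    out = filtered[lo : lo + 2 * half]
    if out.size < 2 * half:  # pad if the peak sits near an edge
        out = np.pad(out, (0, 2 * half - out.size))
    return out


def synthesize_pink_noise(
    n_samples: int,
    sampling_rate: float,
    band: tuple[float, float],
    seed: int,
    *,
    notches: tuple[tuple[float, float], ...] = (),
) -> np.ndarray:
    """Band-limited pink (-3 dB/octave) Gaussian noise, unit total RMS.

    Synthesis is by frequency-domain shaping of white Gaussian noise:
    amplitude proportional to 1/sqrt(f) inside ``band``, zero outside and
    inside any ``notches``. Deterministic given ``seed``.
    """
    _check_rate(sampling_rate, band[1])
    rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n_samples, 1.0 / sampling_rate)
    shape = np.zeros_like(freqs)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    shape[in_band] = 1.0 / np.sqrt(freqs[in_band])
    for lo, hi in notches:
        shape[(freqs > lo) & (freqs < hi)] = 0.0
    spec = shape * (
        rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)
    )
    spec[0] = 0.0
    x = np.fft.irfft(spec, n_samples)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def synthesize_notched_noise(
    spec: NotchedNoise, n_samples: int, sampling_rate: float, seed: int
) -> np.ndarray:
    """Realize ERB-notched pink noise from its band specification."""
    lo = spec.bands[0][0]
    hi = spec.bands[-1][1]
    notches = tuple(
        (spec.bands[i][1], spec.bands[i + 1][0])
        for i in range(len(spec.bands) - 1)
    )
    return synthesize_pink_noise(
        n_samples, sampling_rate, (lo, hi), seed, notches=notches
    )


def synthesize_highpass_masker(
    spec: HighpassMasker, sampling_rate: float, seed: int
) -> np.ndarray:
    """Realize the highpass pink-noise burst with raised-cosine ramps."""
    n = int(round(spec.duration * sampling_rate))
    x = synthesize_pink_noise(n, sampling_rate, spec.band, seed)
    return _raised_cosine_ramps(x, sampling_rate, spec.ramp)


def notched_noise_for_carriers(
    carriers: tuple[float, float] = (600.0, 2000.0),
    outer_band: tuple[float, float] = (20.0, 3000.0),
    spectrum_level: float = 40.0,
) -> NotchedNoise:
    """Notched-noise spec with one-Cam notches around each carrier.

    For the default carriers this yields the three bands
    (20-515, 694-1773, 2253-3000 Hz).
    """
    edges: list[float] = [outer_band[0]]
    for cf in sorted(carriers):
        lo, hi = erb_notch_edges(cf)
        edges += [float(lo), float(hi)]
    edges.append(outer_band[1])
    bands = tuple(
        (edges[i], edges[i + 1]) for i in range(0, len(edges), 2)
    )
    return NotchedNoise(bands=bands, spectrum_level=spectrum_level)
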