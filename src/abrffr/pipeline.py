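"""End-to-end stage runners tying preprocessing to measurement.

These functions are the library's "do the whole thing" surface used by
the command-line interface, by recovery studies and by tests: simulate or
load a recording, preprocess it, and produce measurement rows ready for
the inference tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import abr, ffr, groupdelay
from .preprocess import (
    Recording,
    compensate_trigger_delay,
    epoch,
    fir_bandpass,
    iterative_weighted_average,
)

__all__ = ["ABRConfig", "FFRConfig", "measure_abr", "measure_ffr",
           "env_group_delay"]


@dataclass(frozen=True)
class ABRConfig:
    """Processing parameters for one click run."""

    trigger_delay_s: float = 0.0  # 0.9e-3 for real tube earphones
    filter_band: tuple[float, float] | None = (100.0, 1500.0)
    filter_taps: int = 256
    window_s: tuple[float, float] = (-0.003, 0.012)
    baseline_s: tuple[float, float] = (-0.003, 0.0)
    search_windows_ms: dict = field(
        default_factory=lambda: dict(abr.DEFAULT_SEARCH_WINDOWS)
    )


@dataclass(frozen=True)
class FFRConfig:
    """Processing parameters for one AM-tone run."""

    trigger_delay_s: float = 0.0
    filter_band: tuple[float, float] | None = (60.0, 1000.0)
    filter_taps: int = 256
    window_s: tuple[float, float] = (-0.005, 0.450)
    baseline_s: tuple[float, float] = (-0.005, 0.0)


def _average_by(epochs, key: str, value) -> "np.ndarray":
    subset = epochs.select(**{key: value})
    return iterative_weighted_average(subset)


def measure_abr(
    recording: Recording,
    level: int,
    config: ABRConfig | None = None,
    channel: str | None = None,
) -> dict:
    """Click run -> per-wave peak measurements.

    Preprocess (trigger-delay compensation, optional zero-phase bandpass,
    epoching with baseline correction), average each ear with the
    iterative-weighted average, average the two ears, and pick waves I
    and V. Returns the two :class:`~abrffr.abr.PeakMeasurement` objects
    plus the ear-averaged response.
    """
    config = config or ABRConfig()
    rec = compensate_trigger_delay(recording, config.trigger_delay_s)
    if config.filter_band is not None:
        rec = fir_bandpass(rec, config.filter_band, config.filter_taps)
    epochs = epoch(rec, config.window_s, config.baseline_s, channel=channel)
    for m in epochs.metadata:
        m["ear"] = m["code"].split("/")[1] if "/" in m["code"] else "?"
    left = iterative_weighted_average(epochs.select(ear="L"))
    right = iterative_weighted_average(epochs.select(ear="R"))
    response = abr.average_ears(left, right)
    out = {"response": response, "measurements": {}}
    for wave in ("I", "V"):
        win = config.search_windows_ms[(wave, level)]
        out["measurements"][wave] = abr.pick_wave(response, wave, win)
    return out


def measure_ffr(
    recording: Recording,
    stimulus_config: str,
    config: FFRConfig | None = None,
    channel: str | None = None,
) -> dict:
    """AM-tone run -> ENV/TFS spectral components.

    Preprocess, average per polarity, form addition/subtraction waveforms
    and extract the spectral components for the given CF/MF stimulus
    configuration label (see :data:`abrffr.ffr.STIMULUS_CONFIGS`).
    """
    config = config or FFRConfig()
    rec = compensate_trigger_delay(recording, config.trigger_delay_s)
    if config.filter_band is not None:
        rec = fir_bandpass(rec, config.filter_band, config.filter_taps)
    epochs = epoch(rec, config.window_s, config.baseline_s, channel=channel)
    for m in epochs.metadata:
        parts = m["code"].split("/")
        m["polarity"] = parts[1] if len(parts) > 1 else "?"
    rar = iterative_weighted_average(epochs.select(polarity="rarefaction"))
    con = iterative_weighted_average(epochs.select(polarity="condensation"))
    pair = ffr.PolarityPair(rar, con)
    addition, subtraction = ffr.add_sub(pair)
    comps = ffr.extract_components(addition, subtraction, stimulus_config)
    return {
        "addition": addition,
        "subtraction": subtraction,
        "components": comps,
    }


def env_group_delay(
    components: list[ffr.SpectralComponent],
    carrier: float,
    latency_range_ms=groupdelay.LATENCY_RANGE_MS,
    threshold_db: float = ffr.SNR_INCLUSION_DB,
) -> groupdelay.GroupDelayEstimate | None:
    """ENV latency for one carrier from components across all four MFs.

    Collates the ENV components belonging to ``carrier`` (one per
    modulation frequency, i.e. one per stimulus configuration), enforces
    the all-four-pass SNR rule, and runs the unwrapping fit. Returns
    ``None`` when the rule fails, mirroring how latency data go missing.
    """
    env = sorted(
        (c for c in components if c.kind == "ENV" and c.carrier == carrier),
        key=lambda c: c.freq,
    )
    if len(env) != 4 or not ffr.all_passed(env, threshold_db):
        return None
    ps = groupdelay.PhaseSet(
        freqs=np.array([c.freq for c in env]),
        phases=np.array([c.phase for c in env]),
        source="ENV",
    )
    return groupdelay.estimate_group_delay(ps, latency_range_ms)
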