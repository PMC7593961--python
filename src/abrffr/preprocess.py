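"""Continuous-recording operations shared by the ABR and FFR pipelines.

A :class:`Recording` holds named continuous channels, a sampling rate and
stimulus trigger events. The operations here are deliberately small and
composable: trigger-delay compensation (earphone-tube acoustic delay),
zero-phase FIR bandpass filtering, epoching with baseline correction, and
iterative-weighted averaging of epochs where each epoch (block) is weighted
by the inverse of its residual-noise variance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

logger = logging.getLogger(__name__)

__all__ = [
    "Recording",
    "EpochSet",
    "AveragedResponse",
    "compensate_trigger_delay",
    "fir_bandpass",
    "epoch",
    "iterative_weighted_average",
    "read_edf",
]


@dataclass
class Recording:
    """Continuous multichannel recording with trigger events.

    ``channels`` maps channel name to a 1-D float array (volts); all
    channels share ``sampling_rate`` (Hz). ``triggers`` is a list of
    ``(time_s, code)`` with strictly increasing times; codes are free-form
    strings (e.g. ``"L/rarefaction"``).
    """

    channels: dict[str, np.ndarray]
    sampling_rate: float
    triggers: list[tuple[float, str]] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) > 1:
            raise ValueError("all channels must have equal length")
        times = [t for t, _ in self.triggers]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("trigger times must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def save(self, path) -> None:
        """Write to the documented container: ``.npz`` with a JSON header."""
        import json

        meta = {
            "sampling_rate": self.sampling_rate,
            "triggers": [[t, c] for t, c in self.triggers],
            "meta": self.meta,
            "channel_names": list(self.channels),
        }
        np.savez(
            path,
            __header__=np.frombuffer(
                json.dumps(meta).encode(), dtype=np.uint8
            ),
            **self.channels,
        )

    @classmethod
    def load(cls, path) -> "Recording":
        import json

        with np.load(path) as data:
            meta = json.loads(bytes(data["__header__"]).decode())
            channels = {k: data[k] for k in meta["channel_names"]}
        return cls(
            channels=channels,
            sampling_rate=meta["sampling_rate"],
            triggers=[(float(t), str(c)) for t, c in meta["triggers"]],
            meta=meta.get("meta", {}),
        )


@dataclass
class EpochSet:
    """Stimulus-locked segments on a common time base.

    ``epochs`` is (n_epochs, n_samples); ``times`` gives per-sample time
    relative to the trigger (s). ``metadata`` carries one dict per epoch
    (ear, polarity, stimulus code, ...).
    """

    epochs: np.ndarray
    times: np.ndarray
    metadata: list[dict]
    baseline_corrected: bool = False
    n_dropped: int = 0

    def select(self, **criteria) -> "EpochSet":
        """Subset of epochs whose metadata match all keyword criteria."""
        idx = [
            i
            for i, m in enumerate(self.metadata)
            if all(m.get(k) == v for k, v in criteria.items())
        ]
        return EpochSet(
            epochs=self.epochs[idx],
            times=self.times,
            metadata=[self.metadata[i] for i in idx],
            baseline_corrected=self.baseline_corrected,
            n_dropped=self.n_dropped,
        )

    @property
    def sampling_rate(self) -> float:
        return 1.0 / float(self.times[1] - self.times[0])


@dataclass
class AveragedResponse:
    """Weighted-average evoked response with a residual-noise estimate.

    ``noise_variance`` estimates the variance of the residual noise in the
    *average* (not in single epochs); it is what detectability judgements
    are made against.
    """

    waveform: np.ndarray
    times: np.ndarray
    weights: np.ndarray
    noise_variance: float
    n_epochs: int

    @property
    def sampling_rate(self) -> float:
        return 1.0 / float(self.times[1] - self.times[0])


def compensate_trigger_delay(recording: Recording, delay: float) -> Recording:
    """Shift every trigger forward by ``delay`` seconds, signals untouched.

    Used to compensate the acoustic delay of earphone tubes (0.9 ms for
    the standard insert-earphone setup): the stimulus reaches the eardrum
    ``delay`` seconds after the electrical trigger.
    """
    if delay < 0:
        raise ValueError("delay must be non-negative")
    return replace(
        recording,
        triggers=[(t + delay, c) for t, c in recording.triggers],
    )


def fir_bandpass(
    recording: Recording,
    band: tuple[float, float],
    n_taps: int = 256,
) -> Recording:
    """Zero-phase FIR bandpass of every channel.

    A linear-phase (Hamming-windowed sinc) FIR is applied forward once and
    its exact (N-1)/2-sample group delay removed by shifting, giving zero
    net phase shift at all frequencies without the squared-magnitude
    response of forward-backward filtering. Even tap counts are bumped by
    one so the delay is an integer number of samples.
    """
    nyq = recording.sampling_rate / 2.0
    if not (0 < band[0] < band[1] < nyq):
        raise ValueError(
            f"band {band} must lie strictly inside (0, {nyq}) Hz"
        )
    taps = n_taps + 1 if n_taps % 2 == 0 else n_taps
    h = sps.firwin(taps, band, fs=recording.sampling_rate, pass_zero=False)
    h -= h.sum() / taps  # exact null at DC; negligible passband effect
    shift = (taps - 1) // 2
    out = {}
    for name, x in recording.channels.items():
        y = np.convolve(x, h)[shift : shift + len(x)]
        out[name] = y
    return replace(recording, channels=out)


def epoch(
    recording: Recording,
    window: tuple[float, float],
    baseline: tuple[float, float] | None = None,
    channel: str | None = None,
) -> EpochSet:
    """Segment a channel around each trigger and baseline-correct.

    ``window`` is (t0, t1) seconds relative to the trigger, half-open in
    samples ``[t0, t1)`` with the trigger sample included at t=0.
    ``baseline`` must lie inside ``window``; the per-epoch mean over the
    baseline is subtracted. Triggers whose window extends past the record
    edge are dropped (counted in ``n_dropped``).
    """
    if channel is None:
        channel = next(iter(recording.channels))
    x = recording.channels[channel]
    fs = recording.sampling_rate
    i0 = int(round(window[0] * fs))
    i1 = int(round(window[1] * fs))
    if baseline is not None and not (
        window[0] <= baseline[0] < baseline[1] <= window[1]
    ):
        raise ValueError("baseline must lie inside the epoch window")
    times = np.arange(i0, i1) / fs
    rows, meta, dropped = [], [], 0
    for t, code in recording.triggers:
        c = int(round(t * fs))
        if c + i0 < 0 or c + i1 > len(x):
            dropped += 1
            continue
        rows.append(x[c + i0 : c + i1])
        meta.append({"code": code, "trigger_time": t})
    if dropped:
        logger.info("epoch: dropped %d trigger(s) at record edges", dropped)
    epochs = np.asarray(rows, dtype=float)
    if baseline is not None and epochs.size:
        mask = (times >= baseline[0]) & (times < baseline[1])
        epochs = epochs - epochs[:, mask].mean(axis=1, keepdims=True)
    return EpochSet(
        epochs=epochs,
        times=times,
        metadata=meta,
        baseline_corrected=baseline is not None,
        n_dropped=dropped,
    )


def iterative_weighted_average(
    epochs: np.ndarray | EpochSet,
    *,
    block_size: int = 1,
    tol: float = 1e-6,
    max_iter: int = 50,
) -> AveragedResponse:
    """Average epochs with weights inverse to residual-noise variance.

    Epochs are grouped into consecutive blocks of ``block_size``; each
    block's noise variance is estimated as the temporal variance of the
    block mean minus the current grand estimate, and the grand estimate is
    re-formed as the variance-weighted mean of block means. Iteration
    stops when the relative change of the estimate (RMS, relative to its
    own RMS) falls below ``tol`` or after ``max_iter`` passes.

    The returned ``noise_variance`` is the estimated residual-noise
    variance of the *weighted average*, 1/sum(1/var_b per-epoch scale).
    """
    if isinstance(epochs, EpochSet):
        times = epochs.times
        data = epochs.epochs
    else:
        data = np.asarray(epochs, dtype=float)
        times = np.arange(data.shape[1])
    n = data.shape[0]
    if n == 0:
        raise ValueError("no epochs to average")
    if n == 1:
        warnings.warn(
            "single epoch: returned as-is with infinite noise variance",
            stacklevel=2,
        )
        return AveragedResponse(
            waveform=data[0].copy(),
            times=times,
            weights=np.ones(1),
            noise_variance=np.inf,
            n_epochs=1,
        )
    n_blocks = n // block_size
    # trailing epochs that do not fill a block are folded into the last one
    bounds = [b * block_size for b in range(n_blocks)] + [n]
    block_means = np.stack(
        [data[bounds[b] : bounds[b + 1]].mean(axis=0) for b in range(n_blocks)]
    )
    block_sizes = np.diff(bounds).astype(float)

    def _weights(resid_var: np.ndarray) -> np.ndarray:
        # stable inverse-variance weights; zero-variance blocks (noiseless)
        # share the weight uniformly among themselves
        if resid_var.min() == 0:
            w = (resid_var == 0).astype(float)
        else:
            w = resid_var.min() / resid_var
        return w / w.sum()

    estimate = block_means.mean(axis=0)
    weights = np.full(n_blocks, 1.0 / n_blocks)
    for _ in range(max_iter):
        resid_var = np.var(block_means - estimate, axis=1)
        w = _weights(resid_var)
        new_estimate = w @ block_means
        scale = np.sqrt(np.mean(new_estimate**2))
        delta = np.sqrt(np.mean((new_estimate - estimate) ** 2))
        estimate, weights = new_estimate, w
        if scale == 0 or delta / scale < tol:
            break
    resid_var = np.var(block_means - estimate, axis=1)
    # variance of the weighted mean: block-mean variance scaled by weights;
    # each block mean's own noise variance ~ resid_var (already block level)
    avg_noise_var = float(np.sum(weights**2 * resid_var))
    return AveragedResponse(
        waveform=estimate,
        times=times,
        weights=weights,
        noise_variance=avg_noise_var,
        n_epochs=n,
    )


def read_edf(path, channel_names: list[str] | None = None) -> Recording:
    """Read an EDF file into a :class:`Recording` (requires mne)."""
    import mne  # lazy: EDF input is optional

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    picks = channel_names or raw.ch_names
    data = raw.get_data(picks=picks)
    channels = {name: data[i] for i, name in enumerate(picks)}
    triggers: list[tuple[float, str]] = []
    for ann in raw.annotations:
        triggers.append((float(ann["onset"]), str(ann["description"])))
    return Recording(
        channels=channels,
        sampling_rate=float(raw.info["sfreq"]),
        triggers=triggers,
    )
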