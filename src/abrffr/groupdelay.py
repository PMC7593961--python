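"""Response latency from the phase slope of closely spaced components.

A steady-state response with a single latency tau has component phases
phi(f) = -2*pi*f*tau + phi0, so the group delay -dphi/df / (2*pi) of the
phase-vs-frequency line estimates the latency. Measured phases are only
known modulo 2*pi, so every unwrapping (integer 2*pi adjustment per
component) consistent with latencies in a stated range is enumerated, each
candidate fit by ordinary least squares, and the minimum-MSE fit kept. A
fit is accepted only when the latency lies in the range and the MSE of the
phase residuals (radians^2) is below 0.01.

An independent brute-force oracle (:func:`oracle_grid_delay`) scans tau on
a fine grid minimizing the circular residual sum of squares; it exists so
the enumeration/fit path can be verified against an implementation that
shares none of its machinery.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PhaseSet",
    "GroupDelayEstimate",
    "MSE_CRITERION",
    "LATENCY_RANGE_MS",
    "enumerate_unwrappings",
    "fit_group_delay",
    "estimate_group_delay",
    "oracle_grid_delay",
]

#: Maximum mean squared phase-residual (radians^2) for an accepted fit.
MSE_CRITERION = 0.01

#: Default admissible latency range, ms.
LATENCY_RANGE_MS = (0.0, 30.0)


@dataclass(frozen=True)
class PhaseSet:
    """Component phases at strictly increasing frequencies."""

    freqs: np.ndarray  # Hz
    phases: np.ndarray  # radians, principal branch (-pi, pi]
    source: str = "ENV"  # "ENV" (addition) or "TFS" (subtraction)

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        p = np.asarray(self.phases, dtype=float)
        if f.ndim != 1 or f.shape != p.shape:
            raise ValueError("freqs and phases must be matching 1-D arrays")
        if np.any(np.diff(f) <= 0):
            raise ValueError("freqs must be strictly increasing")
        object.__setattr__(self, "freqs", f)
        object.__setattr__(self, "phases", _wrap(p))


@dataclass(frozen=True)
class GroupDelayEstimate:
    latency_ms: float
    fit_mse: float
    n_candidates_considered: int
    accepted: bool
    at_boundary: bool = False


def _wrap(phi):
    """Wrap angles to the principal branch (-pi, pi]."""
    return -((-np.asarray(phi) + np.pi) % (2 * np.pi) - np.pi)


def enumerate_unwrappings(
    phaseset: PhaseSet,
    latency_range_ms: tuple[float, float] = LATENCY_RANGE_MS,
    *,
    slack_rad: float = np.pi,
) -> list[np.ndarray]:
    """All unwrapped phase vectors consistent with latencies in range.

    The first phase is kept fixed (the intercept is free, so one global
    2*pi offset is irrelevant); each further phase is adjusted by every
    integer multiple of 2*pi that keeps its two-point slope to the first
    component within the slope interval implied by the latency range,
    widened by ``slack_rad`` to admit noisy phases near the range edges.
    Duplicate vectors are removed.
    """
    f = phaseset.freqs
    p = phaseset.phases
    tau_lo, tau_hi = (v * 1e-3 for v in latency_range_ms)
    if tau_hi < tau_lo:
        raise ValueError("latency range must be ordered")
    # slope interval in rad/Hz (negative slopes for positive latency)
    s_lo, s_hi = -2 * np.pi * tau_hi, -2 * np.pi * tau_lo
    choices: list[list[int]] = [[0]]
    for i in range(1, f.size):
        df = f[i] - f[0]
        lo = (s_lo * df - slack_rad - (p[i] - p[0])) / (2 * np.pi)
        hi = (s_hi * df + slack_rad - (p[i] - p[0])) / (2 * np.pi)
        ks = list(range(int(np.ceil(lo)), int(np.floor(hi)) + 1))
        if not ks:
            return []
        choices.append(ks)
    seen, out = set(), []
    for combo in itertools.product(*choices):
        vec = p + 2 * np.pi * np.asarray(combo, dtype=float)
        key = combo
        if key not in seen:
            seen.add(key)
            out.append(vec)
    return out


def fit_group_delay(
    candidates: list[np.ndarray],
    freqs: np.ndarray,
    latency_range_ms: tuple[float, float] = LATENCY_RANGE_MS,
) -> GroupDelayEstimate:
    """OLS phase-vs-frequency fit per candidate; keep the minimum MSE.

    Latency is -slope/(2*pi) in ms. Ties in MSE are broken toward the
    smaller latency so the estimate is deterministic. The estimate is
    accepted only if the latency lies in the admissible range and the MSE
    is below :data:`MSE_CRITERION`.
    """
    f = np.asarray(freqs, dtype=float)
    if not candidates:
        return GroupDelayEstimate(np.nan, np.inf, 0, False)
    X = np.column_stack([np.ones_like(f), f])
    best: tuple[float, float] | None = None  # (mse, latency_ms)
    for vec in candidates:
        coef, *_ = np.linalg.lstsq(X, vec, rcond=None)
        resid = vec - X @ coef
        mse = float(np.mean(resid**2))
        lat = -coef[1] / (2 * np.pi) * 1e3
        if (
            best is None
            or mse < best[0] - 1e-15
            or (abs(mse - best[0]) <= 1e-15 and lat < best[1])
        ):
            best = (mse, float(lat))
    mse, lat = best
    in_range = latency_range_ms[0] <= lat <= latency_range_ms[1]
    accepted = in_range and mse < MSE_CRITERION
    at_boundary = in_range and (
        np.isclose(lat, latency_range_ms[0])
        or np.isclose(lat, latency_range_ms[1])
    )
    return GroupDelayEstimate(lat, mse, len(candidates), accepted, at_boundary)


def estimate_group_delay(
    phaseset: PhaseSet,
    latency_range_ms: tuple[float, float] = LATENCY_RANGE_MS,
) -> GroupDelayEstimate:
    """Convenience: enumerate unwrappings then fit."""
    cands = enumerate_unwrappings(phaseset, latency_range_ms)
    return fit_group_delay(cands, phaseset.freqs, latency_range_ms)


def oracle_grid_delay(
    phaseset: PhaseSet,
    latency_range_ms: tuple[float, float] = LATENCY_RANGE_MS,
    grid_step_ms: float = 0.01,
) -> tuple[float, bool]:
    """Brute-force latency: grid scan of the circular residual sum.

    For each tau on the grid the residuals wrap(phi_i + 2*pi*f_i*tau - mu)
    are computed with mu the circular mean of (phi_i + 2*pi*f_i*tau); the
    returned latency is the argmin of the summed squared residuals.
    Returns ``(latency_ms, at_boundary)``.
    """
    f = phaseset.freqs
    p = phaseset.phases
    taus = np.arange(
        latency_range_ms[0], latency_range_ms[1] + grid_step_ms / 2,
        grid_step_ms,
    ) * 1e-3
    # shape (n_tau, n_comp): phases advanced to remove the delay
    adv = p[None, :] + 2 * np.pi * f[None, :] * taus[:, None]
    mu = np.angle(np.exp(1j * adv).sum(axis=1))
    resid = _wrap(adv - mu[:, None])
    cost = np.sum(resid**2, axis=1)
    i = int(np.argmin(cost))
    lat = taus[i] * 1e3
    boundary = i == 0 or i == taus.size - 1
    return float(lat), boundary
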