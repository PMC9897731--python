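"""Non-negative sparse AR(1) deconvolution of fluorescence traces.

Solves ``min ||F - c||^2 + lam * sum(s)`` with ``s[t] = c[t] - gamma*c[t-1]
>= 0`` (and ``s[0] = c[0] >= 0``) by an online pool-adjacent-violators
scheme.  Event amplitudes are reported in multiples of the whole-trace
fluorescence SD, matching the normalisation used for Z-scoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from fearscope.core import DegenerateInputError, InvalidArgumentError

GAMMA_BOUNDS = (0.5, 0.99)
EVENT_FLOOR_SIGMA = 0.1  # discard events below this multiple of sigma_F


def zscore_trace(trace: np.ndarray) -> np.ndarray:
    """Standardise a trace by its whole-trace mean and sample SD (ddof=1)."""
    trace = np.asarray(trace, dtype=float)
    if trace.size < 2:
        raise InvalidArgumentError("trace must have at least 2 samples")
    sd = trace.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("constant trace has no Z-score")
    return (trace - trace.mean()) / sd


def estimate_ar1(trace: np.ndarray) -> float:
    """Estimate the AR(1) coefficient from the lag-2/lag-1 autocovariance ratio.

    The ratio cancels the white-noise contribution (which only inflates lag
    0).  The estimate is clipped to [0.5, 0.99]; non-positive autocovariances
    (white noise) fall back to the lower bound.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size < 100:
        raise InvalidArgumentError("need >= 100 samples to estimate gamma")
    x = trace - trace.mean()
    acov1 = np.dot(x[:-1], x[1:]) / x.size
    acov2 = np.dot(x[:-2], x[2:]) / x.size
    lo, hi = GAMMA_BOUNDS
    if acov1 <= 0 or acov2 <= 0:
        return lo
    return float(np.clip(acov2 / acov1, lo, hi))


@dataclass
class DeconvolutionResult:
    """Denoised trace plus extracted events for one neuron."""

    gamma: float
    denoised: np.ndarray
    event_times: np.ndarray  # s
    event_amplitudes: np.ndarray  # multiples of sigma_f
    sigma_f: float
    lam: float


def _oasis_ar1(y: np.ndarray, gamma: float, lam: float) -> np.ndarray:
    """Pool-adjacent-violators solver; returns the denoised trace c.

    Works on the shifted target that absorbs the l1 penalty:
    ``ytil[t] = y[t] - lam*(1-gamma)/2`` (last sample ``y[T] - lam/2``).
    """
    n = y.size
    ytil = y - 0.5 * lam * (1.0 - gamma)
    ytil[-1] = y[-1] - 0.5 * lam

    # pools: [value, weight, start, length]
    pools: list[list[float]] = []
    for t in range(n):
        pools.append([ytil[t], 1.0, t, 1])
        while len(pools) > 1:
            prev, cur = pools[-2], pools[-1]
            g_l = gamma ** prev[3]
            if cur[0] > g_l * prev[0]:
                break
            # merge cur into prev
            w_new = prev[1] + g_l * g_l * cur[1]
            prev[0] = (prev[1] * prev[0] + g_l * cur[1] * cur[0]) / w_new
            prev[1] = w_new
            prev[3] += cur[3]
            pools.pop()

    # project the leading pool onto c[0] >= 0, re-merging if that creates
    # new violations downstream
    while pools[0][0] < 0:
        pools[0][0] = 0.0
        if len(pools) > 1 and pools[1][0] <= 0.0:
            first, nxt = pools[0], pools[1]
            first[3] += nxt[3]
            pools.pop(1)
            first[0] = 0.0
        else:
            break

    c = np.empty(n)
    for v, _w, start, length in pools:
        v = max(v, 0.0)
        c[start : start + length] = v * gamma ** np.arange(length)
    return c


def _noise_sd_mad(trace: np.ndarray) -> float:
    """Noise SD via the median absolute deviation of the first difference."""
    d = np.diff(trace)
    return float(np.median(np.abs(d - np.median(d))) / 0.6745 / np.sqrt(2.0))


def _auto_lambda(trace: np.ndarray, gamma: float, max_iter: int = 25) -> float:
    """Bisect lam so the residual SD matches the MAD noise estimate."""
    target = _noise_sd_mad(trace)
    if target == 0:
        return 0.0

    def resid_sd(lam: float) -> float:
        c = _oasis_ar1(trace, gamma, lam)
        return float(np.sqrt(np.mean((trace - c) ** 2)))

    lo, hi = 0.0, 1.0
    while resid_sd(hi) < target and hi < 1e6:
        hi *= 4.0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if resid_sd(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def deconvolve_ar1(
    trace: np.ndarray,
    gamma: float | None = None,
    sparsity_penalty: float | None = None,
    rate: float = 10.0,
    event_floor: float = EVENT_FLOOR_SIGMA,
) -> DeconvolutionResult:
    """Deconvolve one fluorescence trace.

    Parameters
    ----------
    trace : fluorescence samples, arbitrary units.
    gamma : AR(1) coefficient in (0, 1); estimated from the trace if None.
    sparsity_penalty : l1 weight ``lam``; if None, chosen by bisection so the
        residual SD matches a MAD-based noise estimate of the first
        difference.
    rate : sampling rate (Hz), used to convert sample indices to seconds.
    event_floor : minimum event amplitude in multiples of sigma_F.

    Events are the strictly positive increments ``s[t] = c[t] - gamma*c[t-1]``
    exceeding the floor; amplitudes are divided by the whole-trace SD.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size < 2:
        raise InvalidArgumentError("trace must have at least 2 samples")
    if gamma is None:
        gamma = estimate_ar1(trace)
    if not 0.0 < gamma < 1.0:
        raise InvalidArgumentError("gamma must lie in (0, 1)")
    sigma_f = float(trace.std(ddof=1))
    if sigma_f == 0:
        # all-constant trace: no events by definition
        return DeconvolutionResult(
            gamma=gamma,
            denoised=np.zeros_like(trace),
            event_times=np.empty(0),
            event_amplitudes=np.empty(0),
            sigma_f=0.0,
            lam=0.0,
        )
    if sparsity_penalty is None:
        lam = _auto_lambda(trace, gamma)
    else:
        if sparsity_penalty < 0:
            raise InvalidArgumentError("sparsity_penalty must be >= 0")
        lam = float(sparsity_penalty)

    c = _oasis_ar1(trace.copy(), gamma, lam)
    s = np.empty_like(c)
    s[0] = c[0]
    s[1:] = c[1:] - gamma * c[:-1]
    s[np.abs(s) < 1e-12] = 0.0
    keep = s > event_floor * sigma_f
    idx = np.flatnonzero(keep)
    return DeconvolutionResult(
        gamma=float(gamma),
        denoised=c,
        event_times=idx / rate,
        event_amplitudes=s[idx] / sigma_f,
        sigma_f=sigma_f,
        lam=lam,
    )


def deconvolution_objective(
    trace: np.ndarray, c: np.ndarray, gamma: float, lam: float
) -> float:
    """Objective value ``||F - c||^2 + lam * sum(s)`` for a candidate c."""
    s = np.empty_like(c)
    s[0] = c[0]
    s[1:] = c[1:] - gamma * c[:-1]
    return float(np.sum((trace - c) ** 2) + lam * np.sum(s))
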