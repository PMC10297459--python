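"""Bioluminescence detrending and circadian period estimation.

Reporter traces from synchronised cell cultures drift (baseline decay) and
desynchronise (amplitude damping), so the model fitted after baseline
subtraction is a damped cosine A*exp(-lambda*t)*cos(2*pi*t/T + phi).
Baseline subtraction uses a 24 h centred moving average; window endpoints
that land exactly half a window from the centre get half weight (composite
trapezoid), which makes the average of a full-period cosine exactly zero
and cancels a linear trend exactly in the window interior.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, signal

logger = logging.getLogger(__name__)

DEFAULT_BAND = (18.0, 32.0)


@dataclass
class RhythmEstimate:
    """Fitted damped-cosine parameters and rhythmicity verdict."""

    period_h: float
    amplitude: float
    damping_rate: float
    phase_rad: float
    r_squared: float
    rhythmic: bool
    converged: bool
    initial_periods_h: tuple[float, ...] = ()


def _check_uniform(times: np.ndarray) -> float:
    diffs = np.diff(times)
    if len(diffs) == 0 or (diffs <= 0).any():
        raise ValueError("times must be strictly increasing")
    dt = float(diffs[0])
    if not np.allclose(diffs, dt, rtol=1e-9, atol=1e-9 * dt):
        raise ValueError("times must be uniformly spaced")
    return dt


def detrend(times, values, window: float = 24.0) -> np.ndarray:
    """Subtract the centred truncated moving average (trapezoid-weighted).

    The average at t_i runs over samples within [t_i - window/2,
    t_i + window/2] intersected with the record; samples exactly at the
    window edge get half weight.  Output has the same length as the input;
    the first and last window/2 hours are edge-affected (see
    :func:`edge_mask`).
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.shape != values.shape:
        raise ValueError("times and values must have equal length")
    dt = _check_uniform(times)
    span = times[-1] - times[0]
    if window >= span:
        raise ValueError(f"window ({window} h) must be smaller than span ({span} h)")
    half = window / 2.0
    k = int(np.floor(half / dt + 1e-9))
    kernel = np.ones(2 * k + 1)
    if np.isclose(k * dt, half, rtol=1e-9):
        kernel[0] = kernel[-1] = 0.5
    sums = np.convolve(values, kernel, mode="same")
    norms = np.convolve(np.ones_like(values), kernel, mode="same")
    return values - sums / norms


def edge_mask(times, window: float = 24.0) -> np.ndarray:
    """True where the detrending window was truncated by the record edges."""
    times = np.asarray(times, dtype=float)
    half = window / 2.0
    return (times - times[0] < half) | (times[-1] - times < half)


def _periodogram_candidates(
    times: np.ndarray,
    values: np.ndarray,
    band: tuple[float, float],
    n_candidates: int = 3,
) -> list[float]:
    """Dominant periodogram periods inside the search band, best first."""
    dt = _check_uniform(times)
    freqs = np.fft.rfftfreq(len(values), d=dt)
    power = np.abs(np.fft.rfft(values - values.mean())) ** 2
    with np.errstate(divide="ignore"):
        periods = np.where(freqs > 0, 1.0 / freqs, np.inf)
    in_band = (periods >= band[0]) & (periods <= band[1])
    if not in_band.any():
        return [float(np.sqrt(band[0] * band[1]))]
    idx = np.nonzero(in_band)[0]
    order = idx[np.argsort(power[idx])[::-1]]
    return [float(periods[i]) for i in order[:n_candidates]]


def _damped_cosine(t, amplitude, damping, period, phase):
    return amplitude * np.exp(-damping * t) * np.cos(2 * np.pi * t / period + phase)


def fit_damped_cosine(
    times,
    values,
    band: tuple[float, float] = DEFAULT_BAND,
    detrend_first: bool = False,
    window: float = 24.0,
    r_squared_min: float = 0.5,
) -> RhythmEstimate:
    """Least-squares fit of a damped cosine to a (detrended) trace.

    The period is initialised from the dominant periodogram frequencies in
    the search band (multi-start over up to 3 candidates, deterministic)
    and constrained to the band; damping is constrained non-negative.
    ``rhythmic`` requires convergence, r^2 >= ``r_squared_min`` and a
    within-band period.  Non-convergence returns a flagged estimate rather
    than raising.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if band[0] <= 0 or band[1] <= band[0]:
        raise ValueError("search band must satisfy 0 < low < high")
    if detrend_first:
        values = detrend(times, values, window=window)
    t = times - times[0]
    candidates = _periodogram_candidates(t, values, band)

    best = None
    for period0 in candidates:
        amp0 = float(np.sqrt(2.0) * values.std()) or 1.0
        for phase0 in (0.0, np.pi / 2, np.pi, -np.pi / 2):
            p0 = [amp0, 0.01, period0, phase0]
            try:
                popt, _ = optimize.curve_fit(
                    _damped_cosine,
                    t,
                    values,
                    p0=p0,
                    bounds=(
                        [0.0, 0.0, band[0], -2 * np.pi],
                        [np.inf, 1.0, band[1], 2 * np.pi],
                    ),
                    maxfev=20000,
                )
            except RuntimeError:
                continue
            residuals = values - _damped_cosine(t, *popt)
            sse = float(residuals @ residuals)
            if best is None or sse < best[0]:
                best = (sse, popt)

    if best is None:
        logger.warning("damped-cosine fit failed to converge from all starts")
        return RhythmEstimate(
            period_h=float("nan"),
            amplitude=float("nan"),
            damping_rate=float("nan"),
            phase_rad=float("nan"),
            r_squared=0.0,
            rhythmic=False,
            converged=False,
            initial_periods_h=tuple(candidates),
        )

    sse, (amplitude, damping, period, phase) = best
    sst = float(((values - values.mean()) ** 2).sum())
    r_squared = 1.0 - sse / sst if sst > 0 else 0.0
    r_squared = float(min(max(r_squared, 0.0), 1.0))
    rhythmic = bool(r_squared >= r_squared_min and band[0] <= period <= band[1])
    return RhythmEstimate(
        period_h=float(period),
        amplitude=float(amplitude),
        damping_rate=float(damping),
        phase_rad=float(phase),
        r_squared=r_squared,
        rhythmic=rhythmic,
        converged=True,
        initial_periods_h=tuple(candidates),
    )


def estimate_rhythm(
    times,
    values,
    window: float = 24.0,
    band: tuple[float, float] = DEFAULT_BAND,
) -> RhythmEstimate:
    """Standard analysis path: detrend, drop edge-affected samples, fit.

    The first and last window/2 hours have truncated detrending windows
    whose baseline estimate is systematically biased, which drags the
    fitted period; they are excluded from the fit.
    """
    times = np.asarray(times, dtype=float)
    detrended = detrend(times, values, window=window)
    keep = ~edge_mask(times, window=window)
    return fit_damped_cosine(times[keep], detrended[keep], band=band)


def peak_times(times, values, prominence_frac: float = 0.25) -> np.ndarray:
    """Times of local maxima above a prominence floor, in time order.

    Prominence threshold defaults to ``prominence_frac`` of max |value|.
    A flat-topped peak is reported once, at its earliest sample.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        return np.empty(0)
    floor = prominence_frac * float(np.abs(values).max())
    _, props = signal.find_peaks(values, prominence=floor, plateau_size=1)
    return times[props["left_edges"]]
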