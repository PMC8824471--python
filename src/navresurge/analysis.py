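"""Measurement conventions for simulated voltage-clamp traces.

Peak currents are measured as the extremum of |I| in a window (sign
preserved); the persistent component is the mean current over the trailing
5% of a segment and is subtracted before peak and time-constant
measurements, mirroring the digital I_NaP subtraction applied to
experimental records.  Decay time constants use the 1/e crossing of the
persistent-subtracted current, and single-exponential and Boltzmann fits
use deterministic initialization so results are bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .propagation import SimulationTrace

__all__ = [
    "BoltzmannFit",
    "ExponentialFit",
    "measure_peak",
    "persistent_level",
    "subtract_persistent",
    "tau_one_over_e",
    "fit_single_exponential",
    "fit_boltzmann",
]

#: Fraction of a segment's tail used to estimate the persistent level.
PERSISTENT_TAIL_FRACTION = 0.05


@dataclass(frozen=True)
class BoltzmannFit:
    """Fit of y = 1 / (1 + exp((V_half - V) / k)).

    Positive ``slope_mV`` describes a curve rising with depolarization
    (activation); negative ``slope_mV`` a falling curve (availability).
    """

    v_half_mV: float
    slope_mV: float
    residual_sse: float

    def __call__(self, v: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp((self.v_half_mV - np.asarray(v)) / self.slope_mV))


@dataclass(frozen=True)
class ExponentialFit:
    """Fit of y = amplitude * exp(-x / tau) + offset."""

    amplitude: float
    tau_ms: float
    offset: float
    residual_sse: float

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.amplitude * np.exp(-np.asarray(x) / self.tau_ms) + self.offset


def _window_arrays(
    trace: SimulationTrace, window: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    t0, t1 = window
    mask = trace.window_mask(t0, t1)
    if not mask.any():
        raise ValueError(f"window [{t0}, {t1}] ms contains no samples")
    return trace.time_ms[mask], trace.current[mask]


def measure_peak(
    trace: SimulationTrace, window: tuple[float, float]
) -> tuple[float, float]:
    """Extremum of the current (max |I|, sign preserved) in a time window.

    Returns ``(amplitude, time_ms)``.
    """
    t, i = _window_arrays(trace, window)
    k = int(np.argmax(np.abs(i)))
    return float(i[k]), float(t[k])


def persistent_level(
    trace: SimulationTrace,
    window: tuple[float, float],
    tail_fraction: float = PERSISTENT_TAIL_FRACTION,
) -> float:
    """Quasi-steady (persistent) current: mean over the window's trailing tail."""
    t0, t1 = window
    if t1 - t0 < 10.0:
        warnings.warn(
            f"segment of {t1 - t0:.1f} ms is short; persistent level may not be steady",
            stacklevel=2,
        )
    t, i = _window_arrays(trace, window)
    tail_start = t1 - tail_fraction * (t1 - t0)
    tail = i[t >= tail_start - 1e-12]
    return float(tail.mean())


def subtract_persistent(
    trace: SimulationTrace, window: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray, float]:
    """Persistent-subtracted current over a segment window.

    Returns ``(time_ms, adjusted_current, persistent)``: the window's
    samples with the trailing-tail persistent level removed.  Applying the
    subtraction to an already-subtracted trace is a no-op to rounding.
    """
    level = persistent_level(trace, window)
    t, i = _window_arrays(trace, window)
    return t, i - level, level


def tau_one_over_e(
    time_ms: np.ndarray,
    current: np.ndarray,
    peak_time_ms: float | None = None,
) -> float:
    """Decay time constant from the 1/e crossing after the peak.

    ``current`` should already have the persistent level subtracted.  The
    returned tau is the time after the peak at which |I| first falls to
    |I_peak|/e, linearly interpolated between samples.  (1/e retention is
    63.2% decay; the conventional "64% decay" is the same measure, rounded.)
    """
    time_ms = np.asarray(time_ms, dtype=float)
    current = np.asarray(current, dtype=float)
    if peak_time_ms is None:
        k = int(np.argmax(np.abs(current)))
    else:
        k = int(np.argmin(np.abs(time_ms - peak_time_ms)))
    peak = abs(current[k])
    if peak == 0.0:
        raise ValueError("peak current is zero; no decay to measure")
    target = peak / np.e
    decay = np.abs(current[k:])
    below = np.nonzero(decay <= target)[0]
    if len(below) == 0:
        raise ValueError(
            "current never decays to 1/e of its peak within the segment"
        )
    j = int(below[0])
    if j == 0:
        return 0.0
    # linear interpolation between the bracketing samples
    t_hi, t_lo = time_ms[k + j], time_ms[k + j - 1]
    y_hi, y_lo = decay[j], decay[j - 1]
    if y_lo == y_hi:
        t_cross = t_hi
    else:
        t_cross = t_lo + (y_lo - target) / (y_lo - y_hi) * (t_hi - t_lo)
    return float(t_cross - time_ms[k])


def fit_single_exponential(
    x: np.ndarray, y: np.ndarray, with_offset: bool = True
) -> ExponentialFit:
    """Least-squares fit of ``A * exp(-x / tau)`` (+ C with ``with_offset``).

    Initialization is deterministic: A = y[0] - C, C = y[-1] (or 0),
    tau = (x-range)/3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 4:
        raise ValueError(f"need at least 4 points to fit, got {len(x)}")
    if np.allclose(y, y[0]):
        raise ValueError("y is constant; cannot fit an exponential decay")
    span = x[-1] - x[0]
    tau0 = span / 3.0 if span > 0 else 1.0
    try:
        if with_offset:
            c0 = y[-1]
            p0 = [y[0] - c0, tau0, c0]
            popt, _ = curve_fit(
                lambda t, a, tau, c: a * np.exp(-t / tau) + c,
                x, y, p0=p0, maxfev=20000,
            )
            a, tau, c = popt
        else:
            p0 = [y[0], tau0]
            popt, _ = curve_fit(
                lambda t, a, tau: a * np.exp(-t / tau),
                x, y, p0=p0, maxfev=20000,
            )
            a, tau = popt
            c = 0.0
    except RuntimeError as err:
        raise RuntimeError(
            f"exponential fit did not converge (initial guess {p0})"
        ) from err
    resid = y - (a * np.exp(-x / tau) + c)
    if tau <= 0:
        raise RuntimeError(f"exponential fit produced non-positive tau = {tau}")
    return ExponentialFit(
        amplitude=float(a), tau_ms=float(tau), offset=float(c),
        residual_sse=float(np.sum(resid**2)),
    )


def fit_boltzmann(voltage_mV: np.ndarray, y: np.ndarray) -> BoltzmannFit:
    """Least-squares Boltzmann fit ``y = 1 / (1 + exp((V_half - V) / k))``.

    The sign of the fitted slope distinguishes activation (rising with
    depolarization, k > 0) from availability (falling, k < 0).
    """
    v = np.asarray(voltage_mV, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(v) < 5:
        raise ValueError(f"need at least 5 voltages to fit, got {len(v)}")
    if np.min(y) < -0.05 or np.max(y) > 1.05:
        raise ValueError("y must be normalized to [0, 1.05] before fitting")
    if np.ptp(y) < 1e-6:
        raise ValueError("y is flat; cannot fit a Boltzmann function")
    # deterministic initialization: midpoint at half-maximum crossing,
    # slope sign from the overall trend
    rising = y[-1] >= y[0]
    v_half0 = float(v[np.argmin(np.abs(y - 0.5))])
    k0 = 6.0 if rising else -6.0
    try:
        popt, _ = curve_fit(
            lambda vv, vh, k: 1.0 / (1.0 + np.exp((vh - vv) / k)),
            v, y, p0=[v_half0, k0], maxfev=20000,
        )
    except RuntimeError as err:
        raise RuntimeError("Boltzmann fit did not converge") from err
    vh, k = popt
    resid = y - 1.0 / (1.0 + np.exp((vh - v) / k))
    return BoltzmannFit(v_half_mV=float(vh), slope_mV=float(k),
                        residual_sse=float(np.sum(resid**2)))
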