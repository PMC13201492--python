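"""Short-term-plasticity phase compensation at the Purkinje->DCN synapse.

Depression and facilitation act simultaneously on Purkinje->DCN transmission;
when the afferent rate changes, depression re-equilibrates more slowly, so the
net STP contribution at any instant is modelled as a linear function of the
*derivative* of the Purkinje rate.  Net inhibition of a DCN is then

    I(t) = r(t) + k * dr/dt

For a sinusoidal rate wave of angular frequency w this is a sine of the same
wavelength phase-advanced by atan(k*w): when the STP amplitude (k*w*a) equals
the rate amplitude (a), the advance is exactly 45 degrees.  Because
atan(k*w)/w ~ k for small w, the advance measured in *milliseconds* is nearly
wavelength-independent for long cycles — a fixed lead suited to cancelling a
fixed extracerebellar conduction delay.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "STPWaveResult",
    "net_inhibition_wave",
    "measure_time_shift",
    "analytic_shift_ms",
    "shift_vs_wavelength",
]


@dataclass(frozen=True)
class STPWaveResult:
    """Measured phase advance of the net-inhibition wave relative to the rate wave."""

    wavelength_ms: float
    stp_gain_ms: float   # the derivative gain k (units of time)
    shift_ms: float
    shift_deg: float
    shift_pct: float     # percent of one wavelength


def net_inhibition_wave(rate_wave: np.ndarray, k: float,
                        dt_ms: float = 1.0) -> np.ndarray:
    """Sum of the rate wave and ``k`` times its (central-difference) derivative."""
    rate_wave = np.asarray(rate_wave, dtype=float)
    if rate_wave.size < 3:
        raise ValueError("need at least 3 samples to differentiate")
    if (rate_wave <= 0).any():
        raise ValueError("rate wave must be strictly positive")
    return rate_wave + k * np.gradient(rate_wave, dt_ms)


def _advance_samples(x: np.ndarray, y: np.ndarray, max_lag: int) -> float:
    """Time advance of ``y`` over ``x`` in samples, sub-sample refined.

    Uses circular cross-correlation (the waves cover whole cycles, so the
    wrap-around is benign); a positive result means ``y`` leads ``x``.  The
    integer argmax is refined by parabolic interpolation through its two
    circular neighbours.
    """
    x = x - x.mean()
    y = y - y.mean()
    n = x.size
    # c[l] = sum_t x[t] * y[t + l]; y leading by s peaks at l = -s
    c = np.fft.irfft(np.conj(np.fft.rfft(x)) * np.fft.rfft(y), n)
    lags = np.arange(-max_lag, max_lag + 1)
    vals = c[lags % n]
    i = int(np.argmax(vals))
    lag = float(lags[i])
    c_m, c_0, c_p = (c[(lags[i] - 1) % n], vals[i], c[(lags[i] + 1) % n])
    denom = c_m - 2.0 * c_0 + c_p
    if denom != 0:
        lag += 0.5 * (c_m - c_p) / denom
    return -lag


def measure_time_shift(input_wave: np.ndarray, output_wave: np.ndarray,
                       wavelength_ms: float, k: float = float("nan"),
                       dt_ms: float = 1.0) -> STPWaveResult:
    """Locate the output wave's time advance over the input by cross-correlation."""
    input_wave = np.asarray(input_wave, dtype=float)
    output_wave = np.asarray(output_wave, dtype=float)
    if input_wave.size != output_wave.size:
        raise ValueError("waves must have equal length")
    if input_wave.size * dt_ms < 2 * wavelength_ms:
        raise ValueError("waves must cover at least 2 full cycles")
    if np.ptp(input_wave) == 0 or np.ptp(output_wave) == 0:
        raise ValueError("shift undefined for a flat wave")
    max_lag = max(2, int(round(0.5 * wavelength_ms / dt_ms)) - 1)
    shift_ms = _advance_samples(input_wave, output_wave, max_lag) * dt_ms
    shift_deg = 360.0 * shift_ms / wavelength_ms
    return STPWaveResult(wavelength_ms=wavelength_ms, stp_gain_ms=k,
                         shift_ms=shift_ms, shift_deg=shift_deg,
                         shift_pct=100.0 * shift_ms / wavelength_ms)


def analytic_shift_ms(k: float, wavelength_ms: float) -> float:
    """Closed-form advance atan(k*w)/w for a pure sine, in milliseconds."""
    w = 2.0 * math.pi / wavelength_ms
    return math.atan(k * w) / w


def shift_vs_wavelength(wavelengths_ms: list[float], k: float,
                        mean_rate: float = 2.0, amp: float = 1.0,
                        cycles: int = 4, dt_ms: float = 1.0) -> list[STPWaveResult]:
    """Measured STP advance across a wavelength sweep at fixed derivative gain."""
    results = []
    for wl in wavelengths_ms:
        t = np.arange(int(round(cycles * wl / dt_ms))) * dt_ms
        wave = mean_rate + amp * np.sin(2.0 * np.pi * t / wl)
        out = net_inhibition_wave(wave, k, dt_ms)
        results.append(measure_time_shift(wave, out, wl, k=k, dt_ms=dt_ms))
    return results
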