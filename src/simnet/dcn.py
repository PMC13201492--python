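"""Purkinje-to-DCN convergence: spike rasters, rolling readout, reliability.

Purkinje cells fire irregularly, but the spike-discharge *probability* is
synchronized across the microzone.  A DCN reads the shared probability out of
the combined spike count of its 30-50 afferents: convergence plus asynchronous
spike timing turn individually unreadable trains into a smooth, very
high-frequency stream whose short-rolling-window rate is linearly related to
the discharge probability.  This module simulates that at 1 ms resolution and
measures readout reliability as the mean pairwise correlation between
replicate convergent traces.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import NetworkConfig

__all__ = [
    "SpikeRaster",
    "DCNTrace",
    "generate_raster",
    "converge_and_smooth",
    "reliability_curve",
    "dcn_group_rates",
    "sinusoid_rate_curve",
]


@dataclass
class SpikeRaster:
    """Millisecond-binned spike indicators for N afferents sharing one rate curve."""

    spikes: np.ndarray      # (n_afferents, T) of {0, 1}
    prob_curve: np.ndarray  # expected rate (Hz) per 1-ms bin, shared by all afferents
    bin_ms: float = 1.0

    @property
    def n_afferents(self) -> int:
        return self.spikes.shape[0]


@dataclass
class DCNTrace:
    """Combined afferent spike count per bin, smoothed and expected versions."""

    combined_count: np.ndarray
    smoothed: np.ndarray
    expected: np.ndarray
    window_ms: int


def sinusoid_rate_curve(t_ms: int, period_ms: float, low_hz: float = 30.0,
                        high_hz: float = 300.0, phase: float = 0.0) -> np.ndarray:
    """Rate curve fluctuating sinusoidally between ``low_hz`` and ``high_hz``."""
    t = np.arange(t_ms)
    mid = 0.5 * (low_hz + high_hz)
    amp = 0.5 * (high_hz - low_hz)
    return mid + amp * np.sin(phase + 2.0 * np.pi * t / period_ms)


def generate_raster(n_afferents: int, rate_curve: np.ndarray,
                    rng: np.random.Generator) -> SpikeRaster:
    """Independent Bernoulli spikes per afferent per 1-ms bin, p = rate/1000."""
    rate_curve = np.asarray(rate_curve, dtype=float)
    if n_afferents < 1:
        raise ValueError("need at least one afferent")
    if (rate_curve < 0).any() or (rate_curve > 1000.0).any():
        raise ValueError("rates must lie in [0, 1000] Hz for 1-ms Bernoulli bins")
    p = rate_curve / 1000.0
    spikes = (rng.random((n_afferents, rate_curve.size)) < p[None, :]).astype(np.uint8)
    return SpikeRaster(spikes=spikes, prob_curve=rate_curve)


def _rolling_mean(x: np.ndarray, window: int) -> np.ndarray:
    # centred window, shrinking at the sequence ends so no bin is discarded
    return (pd.Series(x).rolling(window, center=True, min_periods=1)
            .mean().to_numpy())


def converge_and_smooth(raster: SpikeRaster, window_ms: int = 2) -> DCNTrace:
    """Sum afferent spikes per bin and apply a centred rolling-average readout."""
    if window_ms < 1:
        raise ValueError("window must be >= 1 ms")
    combined = raster.spikes.sum(axis=0).astype(float)
    smoothed = _rolling_mean(combined, window_ms)
    expected = raster.n_afferents * raster.prob_curve / 1000.0
    return DCNTrace(combined_count=combined, smoothed=smoothed,
                    expected=expected, window_ms=window_ms)


def _mean_pairwise_corr(traces: np.ndarray) -> float:
    cors = [float(np.corrcoef(a, b)[0, 1])
            for a, b in itertools.combinations(traces, 2)]
    return float(np.mean(cors))


def reliability_curve(ratios: list[int], cycles: int, period_ms: float,
                      rng: np.random.Generator, n_replicates: int = 10,
                      window_ms: int = 2, low_hz: float = 30.0,
                      high_hz: float = 300.0) -> pd.DataFrame:
    """Readout reliability vs Purkinje->DCN convergence ratio.

    For each ratio, ``n_replicates`` independent convergent traces are
    simulated over ``cycles`` sinusoidal rate cycles; reliability is the mean
    Pearson correlation over all replicate pairs, reported raw and after the
    rolling-window readout.
    """
    if n_replicates < 2:
        raise ValueError("need >= 2 replicate data sets per ratio")
    t_ms = int(round(cycles * period_ms))
    curve = sinusoid_rate_curve(t_ms, period_ms, low_hz, high_hz)
    rows = []
    for ratio in ratios:
        raw, smooth = [], []
        for _ in range(n_replicates):
            raster = generate_raster(ratio, curve, rng)
            trace = converge_and_smooth(raster, window_ms)
            raw.append(trace.combined_count)
            smooth.append(trace.smoothed)
        rows.append({"ratio": ratio,
                     "corr_raw": _mean_pairwise_corr(np.asarray(raw)),
                     "corr_smoothed": _mean_pairwise_corr(np.asarray(smooth))})
    return pd.DataFrame(rows)


def dcn_group_rates(pc_soma: np.ndarray, cfg: NetworkConfig,
                    rng: np.random.Generator) -> np.ndarray:
    """Normalized firing rates of the 50-cell DCN output group.

    Each DCN averages a with-replacement random sample of 30-50 Purkinje soma
    values and emits the normalized complement (DCN firing is inversely
    related to afferent Purkinje rates).  Averaging narrows: the SD across the
    group is far below the SD across the 400 Purkinje cells.
    """
    pc_soma = np.asarray(pc_soma, dtype=float).ravel()
    if pc_soma.size == 0:
        raise ValueError("empty Purkinje soma data")
    out = np.empty(cfg.dcn_group_size)
    for i in range(cfg.dcn_group_size):
        size = int(rng.integers(cfg.pc_per_dcn_low, cfg.pc_per_dcn_high + 1))
        out[i] = 1.0 - rng.choice(pc_soma, size=size, replace=True).mean()
    return out
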