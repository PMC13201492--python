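"""End-to-end anguilliform-swimming experiment.

During swimming each microstrip receives proprioceptive drive from one
myomere, so the row of 41 strips sees, at any instant, (part of) a sine wave
of input signal frequencies.  This module maps a body-wave fraction and cycle
phase onto per-strip input distributions, runs the full network computation
(granular layer -> molecular layer -> DCN group), and quantifies whether the
50-cell DCN output "reads" the cycle phase: a full body wave cancels across
the strip row (output flat in phase), while a quarter wave survives averaging
and yields phase-locked motor output.

Parallel fibers form about half as many synapses distally as proximally;
:func:`distal_strip_weights` exposes that taper (linear from 1.0 under the
microzone to ``distal_weight_min`` at the outermost strips).  The taper
governs the *relative influence between neighboring networks* — it is not
part of the within-network readout here, and the default pipeline weights all
strips equally.  (A triangular window whose width equals one body wavelength
passes ~12% of the wave's fundamental, so applying it would make a full body
wave partially readable, which is not what the readout does; pass
``strip_weights=distal_strip_weights(cfg)`` to study that regime.)
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import NetworkConfig
from .dcn import dcn_group_rates
from .granular import (GranuleLayerOutput, calibrate_gain, golgi_conversion,
                       granule_activation, microfile_aggregate)
from .inputs import (RateDistributionSpec, normalize_rates, simulate_strip,
                     sine_wave_profile)
from .molecular import MolecularLayerOutput, ParallelFiberCode, molecular_layer

__all__ = [
    "SwimSnapshot",
    "PhaseSweepResult",
    "distal_strip_weights",
    "default_swim_spec",
    "calibrate_swim_gain",
    "run_network",
    "run_swim_snapshot",
    "phase_sweep",
    "sine_fit_r2",
]

# Input-wave geometry: drive oscillates around the middle of the physiological
# mossy-fiber range with an amplitude that keeps every strip's centre inside it.
DEFAULT_MEAN_HZ = 175.0
DEFAULT_AMP_HZ = 75.0
DEFAULT_STRIP_SD_HZ = 25.0
DEFAULT_TARGET_FRACTION = 0.3  # the paper's illustration regime (~30% active)


def default_swim_spec(mean_hz: float = DEFAULT_MEAN_HZ,
                      sd_hz: float = DEFAULT_STRIP_SD_HZ) -> RateDistributionSpec:
    """Per-strip myomere drive: a normal spread around the commanded centre."""
    return RateDistributionSpec(family="normal", mean=mean_hz, sd=sd_hz,
                                low=mean_hz - 4 * sd_hz, high=mean_hz + 4 * sd_hz)


def distal_strip_weights(cfg: NetworkConfig) -> np.ndarray:
    """Per-strip parallel-fiber synaptic weight, tapering with distance."""
    half = (cfg.n_microstrips - 1) // 2
    d = np.abs(np.arange(cfg.n_microstrips) - half)
    return 1.0 - (1.0 - cfg.distal_weight_min) * d / half


@dataclass
class SwimSnapshot:
    """One network's state at one instant of the swimming cycle."""

    phase: float
    wave_fraction: float
    strip_input_mean_hz: np.ndarray
    strip_input_sd_hz: np.ndarray
    input_center_at_microzone_hz: float
    dcn_outputs: np.ndarray          # 50 normalized DCN rates
    gain: float
    molecular: MolecularLayerOutput | None = None

    @property
    def output_mean(self) -> float:
        return float(self.dcn_outputs.mean())


def calibrate_swim_gain(cfg: NetworkConfig, rng: np.random.Generator,
                        target_fraction: float = DEFAULT_TARGET_FRACTION,
                        mean_hz: float = DEFAULT_MEAN_HZ,
                        strip_sd_hz: float = DEFAULT_STRIP_SD_HZ,
                        rel_tol: float = 0.05) -> float:
    """Calibrate the granule gain once, on a strip at the mid-range drive.

    Self-regulation (inhibition tracking the mossy mean) then holds the active
    fraction near the target on every strip of the wave, so one global
    constant serves the whole network and every cycle phase.
    """
    spec = default_swim_spec(mean_hz, strip_sd_hz)
    _, fields = simulate_strip(spec, cfg, rng)
    inh = golgi_conversion(fields, cfg, rng)
    return calibrate_gain(fields, inh, target_fraction, cfg, rng, rel_tol=rel_tol)


def run_network(specs: list[RateDistributionSpec], gain: float,
                cfg: NetworkConfig, rng: np.random.Generator,
                strip_weights: np.ndarray | None = None,
                keep_molecular: bool = False
                ) -> tuple[np.ndarray, MolecularLayerOutput,
                           list[GranuleLayerOutput], pd.DataFrame]:
    """Full network computation for one instant: strips -> microzone -> DCN group.

    Returns the 50 DCN rates, the molecular-layer state, the per-strip granule
    outputs and a per-strip input summary table.
    """
    if len(specs) != cfg.n_microstrips:
        raise ValueError(f"expected {cfg.n_microstrips} strip specs, got {len(specs)}")
    if strip_weights is None:
        strip_weights = np.ones(cfg.n_microstrips)
    strip_outputs: list[GranuleLayerOutput] = []
    summaries = []
    for i, spec in enumerate(specs):
        strip, fields = simulate_strip(spec, cfg, rng, strip_index=i)
        inh = golgi_conversion(fields, cfg, rng)
        strip_outputs.append(granule_activation(fields, inh, gain, cfg, rng=rng))
        summaries.append({"strip": i, "input_mean_hz": float(strip.rates.mean()),
                          "input_sd_hz": float(strip.rates.std()),
                          "active_fraction": strip_outputs[-1].mean_active_fraction})
    aggregates = microfile_aggregate(strip_outputs, cfg, strip_weights=strip_weights)
    pf_codes = [ParallelFiberCode.from_aggregate(a) for a in aggregates]
    mol = molecular_layer(pf_codes, cfg, rng)
    dcn = dcn_group_rates(mol.pc_soma_flat(), cfg, rng)
    return dcn, mol, strip_outputs, pd.DataFrame(summaries)


def run_swim_snapshot(wave_fraction: float, phase: float, cfg: NetworkConfig,
                      rng: np.random.Generator, gain: float | None = None,
                      target_fraction: float = DEFAULT_TARGET_FRACTION,
                      mean_hz: float = DEFAULT_MEAN_HZ,
                      amp_hz: float = DEFAULT_AMP_HZ,
                      strip_sd_hz: float = DEFAULT_STRIP_SD_HZ,
                      keep_molecular: bool = False) -> SwimSnapshot:
    """Simulate one instant of swimming: wave segment in, 50 DCN rates out."""
    if not 0.0 < wave_fraction <= 1.0:
        raise ValueError("wave_fraction must lie in (0, 1]")
    if gain is None:
        gain = calibrate_swim_gain(cfg, rng, target_fraction, mean_hz, strip_sd_hz)
    base = default_swim_spec(mean_hz, strip_sd_hz)
    specs = sine_wave_profile(cfg.n_microstrips, wave_fraction, phase,
                              mean_hz, amp_hz, base)
    dcn, mol, _, summary = run_network(specs, gain, cfg, rng)
    center_idx = (cfg.n_microstrips - 1) // 2
    return SwimSnapshot(
        phase=phase, wave_fraction=wave_fraction,
        strip_input_mean_hz=summary["input_mean_hz"].to_numpy(),
        strip_input_sd_hz=summary["input_sd_hz"].to_numpy(),
        input_center_at_microzone_hz=specs[center_idx].center,
        dcn_outputs=dcn, gain=gain,
        molecular=mol if keep_molecular else None)


@dataclass
class PhaseSweepResult:
    wave_fraction: float
    readability_index: float
    table: pd.DataFrame  # phase, commanded centre, snapshot output mean/sd
    gain: float


def phase_sweep(wave_fraction: float, n_phases: int, cfg: NetworkConfig,
                rng: np.random.Generator, gain: float | None = None,
                target_fraction: float = DEFAULT_TARGET_FRACTION,
                mean_hz: float = DEFAULT_MEAN_HZ, amp_hz: float = DEFAULT_AMP_HZ,
                strip_sd_hz: float = DEFAULT_STRIP_SD_HZ) -> PhaseSweepResult:
    """Sweep the cycle phase and measure how much of it the output codes.

    ``readability_index`` is the range of snapshot-mean outputs across phases
    divided by the range of the commanded (normalized) input centre at the
    microzone: near 0 when a full body wave cancels across the strip row, near
    1 when a quarter wave is faithfully converted into phase-locked output.
    """
    if n_phases < 4:
        raise ValueError("need at least 4 phases")
    if gain is None:
        gain = calibrate_swim_gain(cfg, rng, target_fraction, mean_hz, strip_sd_hz)
    rows = []
    for j in range(n_phases):
        phase = 2.0 * math.pi * j / n_phases
        snap = run_swim_snapshot(wave_fraction, phase, cfg, rng, gain=gain,
                                 mean_hz=mean_hz, amp_hz=amp_hz,
                                 strip_sd_hz=strip_sd_hz)
        rows.append({"phase": phase,
                     "commanded_center_hz": snap.input_center_at_microzone_hz,
                     "output_mean": snap.output_mean,
                     "output_sd": float(snap.dcn_outputs.std())})
    table = pd.DataFrame(rows)
    commanded_norm = normalize_rates(table["commanded_center_hz"].to_numpy(),
                                     cfg.mf_rate_min_hz, cfg.mf_rate_max_hz)
    denom = float(np.ptp(commanded_norm))
    index = float(np.ptp(table["output_mean"].to_numpy()) / denom) if denom > 0 else 0.0
    return PhaseSweepResult(wave_fraction=wave_fraction, readability_index=index,
                            table=table, gain=gain)


def sine_fit_r2(phases: np.ndarray, values: np.ndarray) -> float:
    """R^2 of the least-squares fit of a + b*sin(phase) + c*cos(phase)."""
    phases = np.asarray(phases, dtype=float)
    values = np.asarray(values, dtype=float)
    design = np.column_stack([np.ones_like(phases), np.sin(phases), np.cos(phases)])
    coef, *_ = np.linalg.lstsq(design, values, rcond=None)
    resid = values - design @ coef
    ss_tot = float(((values - values.mean()) ** 2).sum())
    if ss_tot == 0:
        return 1.0
    return 1.0 - float((resid ** 2).sum()) / ss_tot
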