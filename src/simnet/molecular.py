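"""Molecular-layer computation: stellate sampling, Purkinje compartments, inversion.

Each sector of the microzone sits over one microfile and receives that
microfile's parallel-fiber code (the pooled active-granule rate distribution).
Stellate cells sample it (the number of active inputs per cell is binomial in
the regulated active fraction), Purkinje-cell dendritic compartments sample
the stellate rates of the cell's two flanking pools, and the somatic rate is
an excitation/inhibition linear inversion of the integrated drive: both
excitation and inhibition grow linearly with parallel-fiber rates, but
inhibition grows faster, so the net Purkinje response *falls* linearly as
parallel-fiber rates rise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import NetworkConfig
from .granular import MicrofileAggregate

__all__ = [
    "ParallelFiberCode",
    "MolecularLayerOutput",
    "stellate_active_counts",
    "stellate_inputs",
    "stellate_rates",
    "purkinje_compartments",
    "linear_inversion",
    "molecular_layer",
]


@dataclass
class ParallelFiberCode:
    """The parallel-fiber code delivered by one microfile to its sector."""

    microfile_index: int
    rates: np.ndarray          # normalized rates of active parallel fibers
    weights: np.ndarray        # per-rate sampling weight (distal synapse taper)
    active_fraction: float

    @classmethod
    def from_aggregate(cls, agg: MicrofileAggregate) -> "ParallelFiberCode":
        return cls(microfile_index=agg.microfile_index, rates=agg.rates,
                   weights=agg.weights, active_fraction=agg.active_fraction)


def stellate_active_counts(n_cells: int, active_fraction: float,
                           cfg: NetworkConfig, rng: np.random.Generator) -> np.ndarray:
    """Number of active parallel-fiber inputs per stellate cell.

    Each of ``stellate_pf_contacts`` contacts is active independently with the
    regulated probability, so the count is Binomial(contacts, fraction); at a
    sparse code the mean lands in single figures.
    """
    if not 0.0 <= active_fraction <= 1.0:
        raise ValueError("active_fraction must lie in [0, 1]")
    return rng.binomial(cfg.stellate_pf_contacts, active_fraction, size=n_cells)


def _weighted_draws(pf: ParallelFiberCode, total: int,
                    rng: np.random.Generator) -> np.ndarray:
    """``total`` with-replacement draws from the pf rates, weighted by synapse count."""
    if np.allclose(pf.weights, pf.weights[0]):
        return pf.rates[rng.integers(0, pf.rates.size, size=total)]
    cdf = np.cumsum(pf.weights)
    cdf /= cdf[-1]
    return pf.rates[np.searchsorted(cdf, rng.random(total))]


def stellate_inputs(pf: ParallelFiberCode, cfg: NetworkConfig,
                    rng: np.random.Generator,
                    input_fraction: float | None = None) -> list[np.ndarray]:
    """Per-stellate sampled input rate lists for one sector.

    ``input_fraction`` overrides the probability that a contact is active
    (default: the code's own active fraction); it exists because the stellate
    input-count distribution can be prescribed by the regulated sparse
    proportion even when the rate data are illustrated at a denser code.
    """
    counts = stellate_active_counts(
        cfg.stellate_per_sector,
        pf.active_fraction if input_fraction is None else input_fraction,
        cfg, rng)
    if pf.rates.size == 0:
        return [np.empty(0) for _ in counts]
    draws = _weighted_draws(pf, int(counts.sum()), rng)
    return np.split(draws, np.cumsum(counts)[:-1])


def stellate_rates(pf: ParallelFiberCode, cfg: NetworkConfig,
                   rng: np.random.Generator,
                   input_fraction: float | None = None) -> np.ndarray:
    """Stellate somatic rates for one sector: mean of each cell's active inputs.

    Cells with no active input sit at the spontaneous floor rate.
    """
    rates = np.empty(cfg.stellate_per_sector)
    for i, s in enumerate(stellate_inputs(pf, cfg, rng, input_fraction)):
        rates[i] = s.mean() if s.size else cfg.stellate_spontaneous_floor
    return rates


def linear_inversion(pf_drive: np.ndarray | float, r0: float | None = None,
                     ke: float | None = None, ki: float | None = None,
                     cfg: NetworkConfig | None = None) -> np.ndarray | float:
    """Excitation/inhibition inversion: net PC rate falls linearly with drive.

    ``rate = clamp01(r0 + ke*drive - ki*drive)`` with ki > ke >= 0, so the
    response is strictly decreasing in the drive wherever unclamped.
    """
    if cfg is not None:
        r0 = cfg.inversion_r0 if r0 is None else r0
        ke = cfg.inversion_ke if ke is None else ke
        ki = cfg.inversion_ki if ki is None else ki
    if r0 is None or ke is None or ki is None:
        raise ValueError("provide r0, ke, ki (directly or via cfg)")
    if ke < 0 or ki <= ke:
        raise ValueError("inversion requires ki > ke >= 0")
    if not 0.0 < r0 <= 1.0:
        raise ValueError("r0 must lie in (0, 1]")
    return np.clip(r0 + (ke - ki) * np.asarray(pf_drive, dtype=float), 0.0, 1.0)


def purkinje_compartments(sector_stellate: np.ndarray, cfg: NetworkConfig,
                          rng: np.random.Generator,
                          neighbor_stellate: np.ndarray | None = None
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Dendritic-compartment means and somatic inhibition for one sector's PCs.

    Each Purkinje cell has ``stellate_per_pc_inner`` afferent stellate cells,
    half on each side; a compartment averages a random 8-12 sample from one
    side's pool (the PC's own afferents plus the matching afferents of the
    sagittally neighboring sector, reflecting the sagittal reach of stellate
    axons), then averages that with the other side's sample mean.  The somatic
    inhibition is the mean of the compartment means.

    Returns ``(compartments, soma)`` with shapes ``(pc_per_sector,
    pc_compartments)`` and ``(pc_per_sector,)``.
    """
    sector_stellate = np.asarray(sector_stellate, dtype=float)
    if sector_stellate.size == 0:
        raise ValueError("empty stellate pool")
    if neighbor_stellate is None:
        neighbor_stellate = sector_stellate
    n_pc = cfg.pc_per_sector
    per_side = cfg.stellate_per_pc_inner // 2
    s_lo, s_hi = cfg.compartment_stellate_sample_low, cfg.compartment_stellate_sample_high
    n_comp = cfg.pc_compartments

    compartments = np.empty((n_pc, n_comp))
    for pc in range(n_pc):
        side_pools = []
        for source in (sector_stellate, neighbor_stellate):
            own = rng.choice(sector_stellate, size=per_side, replace=False)
            sagittal = rng.choice(source, size=per_side, replace=False)
            side_pools.append(np.concatenate([own, sagittal]))
        for c in range(n_comp):
            means = []
            for pool in side_pools:
                size = int(rng.integers(s_lo, s_hi + 1))
                means.append(rng.choice(pool, size=size, replace=True).mean())
            compartments[pc, c] = 0.5 * (means[0] + means[1])
    soma = compartments.mean(axis=1)
    return compartments, soma


@dataclass
class MolecularLayerOutput:
    """Full molecular-layer state of one microzone."""

    stellate: np.ndarray        # (sectors, stellate_per_sector) normalized rates
    compartments: np.ndarray    # (sectors, pc_per_sector, pc_compartments)
    soma_inhibition: np.ndarray  # (sectors, pc_per_sector)
    pc_soma: np.ndarray         # (sectors, pc_per_sector) post-inversion rates

    def pc_soma_flat(self) -> np.ndarray:
        return self.pc_soma.ravel()

    def soma_inhibition_flat(self) -> np.ndarray:
        return self.soma_inhibition.ravel()

    def stellate_flat(self) -> np.ndarray:
        return self.stellate.ravel()


def molecular_layer(pf_codes: list[ParallelFiberCode], cfg: NetworkConfig,
                    rng: np.random.Generator,
                    input_fraction: float | None = None) -> MolecularLayerOutput:
    """Run stellate sampling, compartment integration and inversion per sector."""
    n_sectors = len(pf_codes)
    if n_sectors != cfg.sectors_per_microzone:
        raise ValueError(f"expected {cfg.sectors_per_microzone} microfiles, got {n_sectors}")
    stellate = np.stack([stellate_rates(pf, cfg, rng, input_fraction)
                         for pf in pf_codes])
    compartments = np.empty((n_sectors, cfg.pc_per_sector, cfg.pc_compartments))
    soma_inh = np.empty((n_sectors, cfg.pc_per_sector))
    for s in range(n_sectors):
        neighbor = stellate[s + 1 if s + 1 < n_sectors else s - 1]
        comp, soma = purkinje_compartments(stellate[s], cfg, rng,
                                           neighbor_stellate=neighbor)
        compartments[s] = comp
        soma_inh[s] = soma
    pc_soma = linear_inversion(soma_inh, cfg=cfg)
    return MolecularLayerOutput(stellate=stellate, compartments=compartments,
                                soma_inhibition=soma_inh, pc_soma=pc_soma)
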