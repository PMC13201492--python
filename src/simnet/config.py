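"""Anatomical constants of a cerebellar locomotor network and derived quantities.

A "network" here is the junction of ~40 granular-layer microstrips (the input
layer), one molecular-layer microzone (the middle layer), and one deep
cerebellar nuclear (DCN) cell group (the output layer).  :class:`NetworkConfig`
is the single source of anatomical truth for every simulation stage; no
downstream module hard-codes a count or a ratio.

Two strip-count conventions coexist in the anatomy.  A microzone receives
parallel fibers from 20 microstrips on each side *plus* the strip directly
beneath it, i.e. 41 afferent strips, and that is what the simulation wires up
(``n_microstrips``).  Field-count bookkeeping ("4,000 fields per network") uses
the nominal 40-strip count (20 per side); the accessors below document which
convention each derived quantity applies.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "NetworkConfig",
    "fields_per_network",
    "microzones_reached_per_microstrip",
    "duplication_cost_fraction",
    "shared_pf_fraction",
    "pf_per_microfile",
    "pf_contacts_per_pc",
    "golgi_ensemble_span_fields",
    "max_combined_dcn_rate",
    "strip_mf_count",
    "clusters_per_field",
    "pc_working_contacts",
    "expected_duplicate_fraction",
    "describe",
]


@dataclass(frozen=True)
class NetworkConfig:
    """All anatomical constants of one network, with validation.

    Counts are strictly positive integers, fractions live in [0, 1], and
    (low, high) range fields satisfy low <= high.  Defaults are the mid-range
    literature estimates used throughout the simulation.
    """

    # --- input layer geometry -------------------------------------------------
    n_microstrips: int = 41           # afferent strips incl. the one beneath the microzone
    fields_per_microstrip: int = 100
    mf_per_field: int = 180           # mossy fibers contributing terminals to a field
    terminals_per_field: int = 700    # also the glomerulus count per field
    terminals_per_cluster_mean: float = 7.5
    cluster_size_low: int = 7
    cluster_size_high: int = 8
    branches_per_mf_per_microstrip: float = 4.5
    straddle_max_fraction: float = 0.3  # max share of a cluster spilling into a neighbor field

    # --- Golgi cells / glomeruli ---------------------------------------------
    golgi_per_field: int = 10
    golgi_basal_dendrites: int = 5
    mf_per_golgi_dendrite: int = 4
    glomerulus_golgi_sample_low: int = 8
    glomerulus_golgi_sample_high: int = 12

    # --- granule cells ---------------------------------------------------------
    granule_per_field: int = 8750
    granule_dendrites: int = 4        # admissible 3-5; each contacts a distinct glomerulus
    min_dominant_inputs: int = 3

    # --- geometry (micrometres) -----------------------------------------------
    pf_halflength_um: float = 3000.0
    microzone_length_um: float = 20000.0
    microzone_width_um: float = 150.0
    field_sagittal_um: float = 200.0
    field_mediolateral_um: float = 150.0

    # --- molecular layer --------------------------------------------------------
    sectors_per_microzone: int = 100
    pc_per_sector: int = 4
    stellate_per_sector: int = 80
    stellate_per_pc_inner: int = 16   # 8 on each side of the PC's sagittal plane
    pf_passing_pc: int = 350_000
    pf_contact_fraction: float = 0.5
    silent_synapse_fraction: float = 0.825  # range 0.80-0.85
    stellate_pf_contacts: int = 1000
    stellate_spontaneous_floor: float = 0.1  # normalized rate for cells with no active input
    pc_compartments: int = 16
    compartment_stellate_sample_low: int = 8
    compartment_stellate_sample_high: int = 12

    # --- excitation/inhibition inversion at the PC soma ------------------------
    inversion_r0: float = 1.0
    inversion_ke: float = 0.5
    inversion_ki: float = 1.5

    # --- output layer -----------------------------------------------------------
    dcn_group_size: int = 50
    pc_per_dcn_low: int = 30
    pc_per_dcn_high: int = 50
    pc_per_dcn_mean: int = 45
    boutons_per_pc_low: int = 24
    boutons_per_pc_high: int = 36

    # --- firing-rate scales (Hz) ------------------------------------------------
    mf_rate_min_hz: float = 50.0
    mf_rate_max_hz: float = 300.0
    pc_rate_min_hz: float = 30.0
    pc_rate_max_hz: float = 300.0

    # --- parallel-fiber distal synapse taper ------------------------------------
    distal_weight_min: float = 0.5    # relative synapse count at the outermost strip

    def __post_init__(self) -> None:
        counts = {
            "n_microstrips": self.n_microstrips,
            "fields_per_microstrip": self.fields_per_microstrip,
            "mf_per_field": self.mf_per_field,
            "terminals_per_field": self.terminals_per_field,
            "golgi_per_field": self.golgi_per_field,
            "golgi_basal_dendrites": self.golgi_basal_dendrites,
            "mf_per_golgi_dendrite": self.mf_per_golgi_dendrite,
            "granule_per_field": self.granule_per_field,
            "granule_dendrites": self.granule_dendrites,
            "min_dominant_inputs": self.min_dominant_inputs,
            "sectors_per_microzone": self.sectors_per_microzone,
            "pc_per_sector": self.pc_per_sector,
            "stellate_per_sector": self.stellate_per_sector,
            "stellate_per_pc_inner": self.stellate_per_pc_inner,
            "pf_passing_pc": self.pf_passing_pc,
            "stellate_pf_contacts": self.stellate_pf_contacts,
            "pc_compartments": self.pc_compartments,
            "dcn_group_size": self.dcn_group_size,
            "pc_per_dcn_mean": self.pc_per_dcn_mean,
        }
        for name, value in counts.items():
            if int(value) != value or value <= 0:
                raise ValueError(f"{name} must be a strictly positive integer, got {value!r}")
        fractions = {
            "pf_contact_fraction": self.pf_contact_fraction,
            "silent_synapse_fraction": self.silent_synapse_fraction,
            "straddle_max_fraction": self.straddle_max_fraction,
            "distal_weight_min": self.distal_weight_min,
        }
        for name, value in fractions.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value!r}")
        ranges = {
            "cluster_size": (self.cluster_size_low, self.cluster_size_high),
            "glomerulus_golgi_sample": (self.glomerulus_golgi_sample_low, self.glomerulus_golgi_sample_high),
            "compartment_stellate_sample": (self.compartment_stellate_sample_low, self.compartment_stellate_sample_high),
            "pc_per_dcn": (self.pc_per_dcn_low, self.pc_per_dcn_high),
            "boutons_per_pc": (self.boutons_per_pc_low, self.boutons_per_pc_high),
            "mf_rate": (self.mf_rate_min_hz, self.mf_rate_max_hz),
            "pc_rate": (self.pc_rate_min_hz, self.pc_rate_max_hz),
        }
        for name, (low, high) in ranges.items():
            if low > high:
                raise ValueError(f"{name} range has low > high: ({low}, {high})")
        for name in ("pf_halflength_um", "microzone_length_um", "microzone_width_um",
                     "field_sagittal_um", "field_mediolateral_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_dominant_inputs > self.granule_dendrites:
            raise ValueError("min_dominant_inputs cannot exceed granule_dendrites")
        if not math.isclose(self.fields_per_microstrip * self.field_sagittal_um,
                            self.microzone_length_um, rel_tol=1e-9):
            raise ValueError(
                "geometry inconsistency: fields_per_microstrip x field_sagittal_um "
                f"({self.fields_per_microstrip * self.field_sagittal_um}) != microzone_length_um "
                f"({self.microzone_length_um})")
        if self.inversion_ki <= self.inversion_ke:
            raise ValueError("inversion requires ki > ke (inhibition gains faster than excitation)")

    # ---- nominal strip-count conventions -------------------------------------
    @property
    def afferent_strips(self) -> int:
        """Strips providing parallel fibers to the microzone: 20 per side + center."""
        return self.n_microstrips

    @property
    def afferent_strips_nominal(self) -> int:
        """The 40-strip convention (20 per side) used for field-count bookkeeping."""
        return self.n_microstrips - 1

    # ---- (de)serialization ----------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def replace(self, **changes: Any) -> "NetworkConfig":
        return dataclasses.replace(self, **changes)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "NetworkConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "NetworkConfig":
        """Load from YAML or JSON (YAML is a superset, so one loader serves both)."""
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if data is None:
            return cls()
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


# ---------------------------------------------------------------------------
# Derived geometric / cost quantities.  All are pure functions of the config.
# ---------------------------------------------------------------------------

def fields_per_network(cfg: NetworkConfig) -> int:
    """Total fields feeding one microzone, on the nominal 40-strip convention."""
    return cfg.afferent_strips_nominal * cfg.fields_per_microstrip


def microzones_reached_per_microstrip(cfg: NetworkConfig) -> int:
    """Microzones reached by one microstrip's parallel fibers (both directions)."""
    if cfg.microzone_width_um <= 0:
        raise ValueError("microzone width must be positive")
    return 2 * math.floor(cfg.pf_halflength_um / cfg.microzone_width_um)


def duplication_cost_fraction(cfg: NetworkConfig) -> float:
    """Percent of granule cells attributable to receiving duplicate signal copies.

    Terminal clustering (mean ~7.5 terminals per cluster) and terminal
    branching (~4.5 branches per mossy fiber per microstrip) multiply the
    number of granule cells needed per distinct signal; only the reciprocal of
    that product serves non-duplicated signal.
    """
    product = cfg.terminals_per_cluster_mean * cfg.branches_per_mf_per_microstrip
    if product < 1:
        raise ValueError("terminals_per_cluster_mean x branches_per_mf must be >= 1")
    return 100.0 * (1.0 - 1.0 / product)


def shared_pf_fraction(cfg: NetworkConfig, offset_strips: int) -> float:
    """Percent of parallel fibers shared by two microzones ``offset_strips`` apart.

    Both microzones draw on ``afferent_strips`` (41) strips; the shared count
    declines linearly with offset and reaches zero when the afferent regions
    are disjoint.
    """
    if offset_strips < 0:
        raise ValueError("offset must be non-negative")
    s = cfg.afferent_strips
    return 100.0 * max(0, s - offset_strips) / s


def pf_per_microfile(cfg: NetworkConfig) -> int:
    """Parallel fibers reaching the microzone from one microfile (40-strip nominal)."""
    return cfg.granule_per_field * cfg.afferent_strips_nominal


def pf_contacts_per_pc(cfg: NetworkConfig) -> float:
    """Parallel fibers making synaptic contact on one Purkinje cell."""
    return cfg.pf_passing_pc * cfg.pf_contact_fraction


def golgi_ensemble_span_fields(cfg: NetworkConfig, row_length: int = 3,
                               cell_span_fields: int = 3) -> int:
    """Sagittal span (in fields) of the union of axonal territories of a Golgi row.

    Each cell's plexus covers ``cell_span_fields`` centred on its own field, so
    a contiguous ``row_length``-field row of cells covers row + span - 1 fields.
    """
    if row_length < 1 or cell_span_fields < 1:
        raise ValueError("row_length and cell_span_fields must be >= 1")
    return row_length + cell_span_fields - 1


def max_combined_dcn_rate(cfg: NetworkConfig) -> float:
    """Upper bound of the combined Purkinje spike rate converging on one DCN (Hz)."""
    return cfg.pc_per_dcn_mean * cfg.pc_rate_max_hz


def strip_mf_count(cfg: NetworkConfig) -> int:
    """Distinct mossy fibers afferent to one microstrip.

    Each fiber branches ~4.5 times within a strip, so the distinct count is
    (fibers per field x fields) / branches per fiber, ~4000 by default.
    """
    return round(cfg.mf_per_field * cfg.fields_per_microstrip
                 / cfg.branches_per_mf_per_microstrip)


def clusters_per_field(cfg: NetworkConfig) -> int:
    """Terminal clusters per field: 700 terminals at ~7.5 terminals each -> 93."""
    return round(cfg.terminals_per_field / cfg.terminals_per_cluster_mean)


def pc_working_contacts(cfg: NetworkConfig) -> float:
    """Parallel-fiber contacts per PC at synapses capable of transmission.

    The learned working:silent synaptic ratio enters the passive computation
    only as this multiplicative factor on the effective contact count.
    """
    return pf_contacts_per_pc(cfg) * (1.0 - cfg.silent_synapse_fraction)


def expected_duplicate_fraction(n_draws: int, pool_size: int) -> float:
    """Expected fraction of repeat selections when drawing with replacement.

    E[distinct] = N(1 - (1 - 1/N)^n); duplicates are the rest.
    """
    if n_draws <= 0 or pool_size <= 0:
        raise ValueError("n_draws and pool_size must be positive")
    expected_distinct = pool_size * (1.0 - (1.0 - 1.0 / pool_size) ** n_draws)
    return 1.0 - expected_distinct / n_draws


def describe(cfg: NetworkConfig) -> dict[str, float]:
    """All derived quantities as a flat JSON-serializable mapping."""
    return {
        "fields_per_network": fields_per_network(cfg),
        "microzones_reached_per_microstrip": microzones_reached_per_microstrip(cfg),
        "duplication_cost_pct": duplication_cost_fraction(cfg),
        "shared_pf_pct_offset_1": shared_pf_fraction(cfg, 1),
        "pf_per_microfile": pf_per_microfile(cfg),
        "pf_contacts_per_pc": pf_contacts_per_pc(cfg),
        "pc_working_contacts": pc_working_contacts(cfg),
        "golgi_ensemble_span_fields": golgi_ensemble_span_fields(cfg),
        "max_combined_dcn_rate_hz": max_combined_dcn_rate(cfg),
        "strip_mf_count": strip_mf_count(cfg),
        "clusters_per_field": clusters_per_field(cfg),
    }
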