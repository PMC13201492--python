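"""Synthetic mossy-fiber input generation.

Three generators live here:

* :func:`draw_strip_rates` — a snapshot of mossy-fiber firing rates received by
  one microstrip, drawn from a parameterized frequency distribution
  (uniform / normal / bimodal / discontinuous / constant) clipped to the
  physiological range (50-300 Hz by default).
* :func:`derive_field_rates` — the per-field "copies-added" rate populations.
  Each field samples the strip's fiber population; terminal clustering
  duplicates each sampled rate ~7-8 times, and clusters straddling a field
  boundary spill part of their copies into the adjacent field.  Copies add no
  new rate values, only multiplicity.
* :func:`sine_wave_profile` — per-strip distribution specs whose centers trace
  a (partial) sine wave across the strip row, emulating the instantaneous
  pattern of proprioceptive drive during anguilliform swimming.

All randomness flows through an explicit :class:`numpy.random.Generator`, so a
seed reproduces every downstream stage byte-for-byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .config import NetworkConfig, clusters_per_field, strip_mf_count

__all__ = [
    "RateDistributionSpec",
    "MicrostripRates",
    "FieldRates",
    "draw_strip_rates",
    "derive_field_rates",
    "sine_wave_profile",
    "normalize_rates",
    "denormalize_rates",
]

_FAMILIES = {"uniform", "normal", "bimodal", "discontinuous", "constant"}


@dataclass(frozen=True)
class RateDistributionSpec:
    """Parameterized mossy-fiber rate distribution.

    ``low``/``high`` are both the support bounds of the uniform/discontinuous
    families and the clipping range applied to every family.  ``mean``/``sd``
    parameterize the normal family; the bimodal family is an equal mixture of
    two normals with the given ``sd`` centred ``separation`` apart around
    ``mean``; the discontinuous family is uniform on [low, high] with the open
    interval (gap_low, gap_high) excised.
    """

    family: str = "uniform"
    low: float = 50.0
    high: float = 300.0
    mean: float | None = None
    sd: float | None = None
    separation: float | None = None
    gap_low: float | None = None
    gap_high: float | None = None
    value: float | None = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown distribution family {self.family!r}; "
                             f"expected one of {sorted(_FAMILIES)}")
        if self.low < 0 or self.low > self.high:
            raise ValueError("require 0 <= low <= high")
        if self.family == "normal" and (self.mean is None or self.sd is None):
            raise ValueError("normal family requires mean and sd")
        if self.family == "bimodal" and (self.mean is None or self.sd is None
                                         or self.separation is None):
            raise ValueError("bimodal family requires mean, sd and separation")
        if self.family == "discontinuous" and (self.gap_low is None or self.gap_high is None):
            raise ValueError("discontinuous family requires gap_low and gap_high")
        if self.family == "constant" and self.value is None:
            raise ValueError("constant family requires value")

    @property
    def center(self) -> float:
        """Location parameter of the family (mean of the untruncated law)."""
        if self.family == "constant":
            return float(self.value)  # type: ignore[arg-type]
        if self.family in ("normal", "bimodal"):
            return float(self.mean)  # type: ignore[arg-type]
        return 0.5 * (self.low + self.high)

    def with_center(self, center: float) -> "RateDistributionSpec":
        """Translate the whole distribution (including its clip bounds).

        Shifting bounds along with the center preserves the distribution's
        shape exactly, which keeps translation families genuinely affine for
        the linear-tracking analyses.
        """
        shift = center - self.center
        kwargs: dict = {"low": self.low + shift, "high": self.high + shift}
        if self.mean is not None:
            kwargs["mean"] = self.mean + shift
        if self.gap_low is not None:
            kwargs["gap_low"] = self.gap_low + shift
        if self.gap_high is not None:
            kwargs["gap_high"] = self.gap_high + shift
        if self.value is not None:
            kwargs["value"] = self.value + shift
        return replace(self, **kwargs)

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if n <= 0:
            raise ValueError("n must be positive")
        if self.family == "constant":
            out = np.full(n, float(self.value))
        elif self.family == "uniform":
            out = rng.uniform(self.low, self.high, n)
        elif self.family == "normal":
            out = rng.normal(self.mean, self.sd, n)
        elif self.family == "bimodal":
            centers = np.where(rng.random(n) < 0.5,
                               self.mean - self.separation / 2.0,
                               self.mean + self.separation / 2.0)
            out = rng.normal(centers, self.sd)
        else:  # discontinuous: uniform with a gap, sampled piecewise
            gl = max(self.low, float(self.gap_low))
            gh = min(self.high, float(self.gap_high))
            if gl >= gh:  # gap outside support -> plain uniform
                out = rng.uniform(self.low, self.high, n)
            else:
                left = gl - self.low
                right = self.high - gh
                if left + right <= 0:
                    raise ValueError("discontinuous gap covers the whole support")
                take_left = rng.random(n) < left / (left + right)
                out = np.where(take_left,
                               rng.uniform(self.low, gl, n),
                               rng.uniform(gh, self.high, n))
        return np.clip(out, self.low, self.high)


@dataclass
class MicrostripRates:
    """Mossy-fiber firing-rate snapshot of one microstrip."""

    strip_index: int
    rates: np.ndarray  # Hz, one per distinct afferent mossy fiber

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rates.size == 0:
            raise ValueError("a microstrip must receive at least one mossy fiber")


@dataclass
class FieldRates:
    """Copies-added rate population of one field (~1 value per glomerulus)."""

    field_index: int
    rates_with_copies: np.ndarray  # Hz

    def __post_init__(self) -> None:
        self.rates_with_copies = np.asarray(self.rates_with_copies, dtype=float)


def normalize_rates(rates: np.ndarray | float, lo: float, hi: float):
    """Affine map from the firing-rate scale [lo, hi] Hz onto [0, 1]."""
    return (np.asarray(rates, dtype=float) - lo) / (hi - lo)


def denormalize_rates(values: np.ndarray | float, lo: float, hi: float):
    return np.asarray(values, dtype=float) * (hi - lo) + lo


def draw_strip_rates(spec: RateDistributionSpec, n_mf: int,
                     rng: np.random.Generator, strip_index: int = 0) -> MicrostripRates:
    """Draw ``n_mf`` i.i.d. mossy-fiber rates for one microstrip."""
    if n_mf <= 0:
        raise ValueError("n_mf must be positive")
    return MicrostripRates(strip_index=strip_index, rates=spec.draw(n_mf, rng))


def derive_field_rates(strip: MicrostripRates, cfg: NetworkConfig,
                       rng: np.random.Generator) -> list[FieldRates]:
    """Derive the per-field copies-added rate populations of a microstrip.

    For each of the ``fields_per_microstrip`` fields: the field's fiber
    complement is a with-replacement sample of ``mf_per_field`` rates from the
    strip population; ~``terminals_per_field / terminals_per_cluster_mean``
    clusters are then drawn from that complement, each contributing 7 or 8
    copies of its rate.  Each cluster spills a uniform-random 0-30% of its
    copies into one adjacent field (strip ends spill inward only), so the
    per-field total stays within about +/-20% of ``terminals_per_field``.
    """
    n_fields = cfg.fields_per_microstrip
    n_clusters = clusters_per_field(cfg)
    pools: list[list[np.ndarray]] = [[] for _ in range(n_fields)]
    for i in range(n_fields):
        field_mf = rng.choice(strip.rates, size=cfg.mf_per_field, replace=True)
        cluster_rates = rng.choice(field_mf, size=n_clusters, replace=True)
        sizes = rng.integers(cfg.cluster_size_low, cfg.cluster_size_high + 1,
                             size=n_clusters)
        spill = np.floor(rng.uniform(0.0, cfg.straddle_max_fraction, n_clusters)
                         * sizes).astype(int)
        if i == 0:
            neighbors = np.ones(n_clusters, dtype=int)
        elif i == n_fields - 1:
            neighbors = np.full(n_clusters, -1)
        else:
            neighbors = rng.choice([-1, 1], size=n_clusters)
        kept = sizes - spill
        pools[i].append(np.repeat(cluster_rates, kept))
        for j in (-1, 1):
            mask = (neighbors == j) & (spill > 0)
            if mask.any():
                pools[i + j].append(np.repeat(cluster_rates[mask], spill[mask]))
    return [FieldRates(field_index=i, rates_with_copies=np.concatenate(pool))
            for i, pool in enumerate(pools)]


def sine_wave_profile(n_strips: int, wave_fraction: float, phase: float,
                      mean_hz: float, amp_hz: float,
                      spec: RateDistributionSpec) -> list[RateDistributionSpec]:
    """Per-strip distribution specs tracing (part of) a sine wave.

    The row of ``n_strips`` strips spans ``wave_fraction`` of one full body
    wavelength: strip ``i`` is centred on
    ``mean_hz + amp_hz * sin(phase + 2*pi*wave_fraction*i/(n_strips-1))``.
    The per-strip spread (family, sd, width) is taken from ``spec``.
    """
    if n_strips < 2:
        raise ValueError("need at least 2 strips to lay out a wave")
    if not 0.0 < wave_fraction <= 1.0:
        raise ValueError("wave_fraction must lie in (0, 1]")
    centers = [mean_hz + amp_hz * math.sin(phase + 2.0 * math.pi * wave_fraction
                                           * i / (n_strips - 1))
               for i in range(n_strips)]
    return [spec.with_center(c) for c in centers]


def simulate_strip(spec: RateDistributionSpec, cfg: NetworkConfig,
                   rng: np.random.Generator, strip_index: int = 0
                   ) -> tuple[MicrostripRates, list[FieldRates]]:
    """Convenience: one strip's fiber snapshot plus its copies-added fields."""
    strip = draw_strip_rates(spec, strip_mf_count(cfg), rng, strip_index)
    return strip, derive_field_rates(strip, cfg, rng)
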