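"""Granular-layer recoding: Golgi ensemble conversion and granule activation.

The granular layer converts the mossy-fiber rate distribution received by a
microstrip into a regulated, narrowed distribution of granule-cell (and hence
parallel-fiber) firing rates.  Two chained random-sampling stages do the work:

1. **Golgi ensemble conversion** — each Golgi cell's 5 basal dendrites average
   4 local mossy-fiber terminal rates; the soma averages its dendrites; each
   glomerulus of the middle field of a 3-field row then averages a random
   sample of 8-12 Golgi somatic rates from the 30-cell ensemble.  Every stage
   is a mean of a random sample, so each narrows the distribution (central
   limit theorem) while leaving the mean linearly coupled to the mossy-fiber
   mean.  The glomerular output is the spillover inhibition applied to granule
   cells.

2. **Granule activation** — each granule cell's dendrites contact distinct
   glomeruli; an input is *dominant* when its excitation beats ``gain x`` the
   inhibition in its own glomerulus, and the cell fires (at the mean of its
   dominant inputs) when at least ``min_dominant_inputs`` dendrites are
   dominant.  Because inhibition tracks the mossy mean, the active fraction
   self-regulates; :func:`calibrate_gain` sets the single global gain constant
   that fixes the regulated fraction.

All computation is on the normalized [0, 1] rate scale (affine image of the
mossy-fiber physiological range), clamped so that rates outside the scale
saturate rather than carry negative drive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import NetworkConfig
from .inputs import FieldRates, normalize_rates

__all__ = [
    "GolgiFieldOutput",
    "GolgiEnsembleOutput",
    "GranuleLayerOutput",
    "MicrofileAggregate",
    "golgi_conversion",
    "draw_granule_wiring",
    "granule_activation",
    "calibrate_gain",
    "microfile_aggregate",
    "CalibrationError",
]


def _normalized_field_rates(fields: list[FieldRates], cfg: NetworkConfig) -> list[np.ndarray]:
    lo, hi = cfg.mf_rate_min_hz, cfg.mf_rate_max_hz
    return [np.clip(normalize_rates(f.rates_with_copies, lo, hi), 0.0, 1.0)
            for f in fields]


@dataclass
class GolgiFieldOutput:
    """Golgi-stage data for one field (all on the normalized scale)."""

    field_index: int
    dendritic_means: np.ndarray       # (golgi_per_field, basal_dendrites)
    golgi_rates: np.ndarray           # somatic rates of this field's own cells
    ensemble_rates: np.ndarray        # somatic rates of the covering 3-field ensemble
    glomerular_inhibition: np.ndarray  # one value per glomerulus of this field


@dataclass
class GolgiEnsembleOutput:
    per_field: list[GolgiFieldOutput]

    def all_dendritic_means(self) -> np.ndarray:
        return np.concatenate([f.dendritic_means.ravel() for f in self.per_field])

    def all_golgi_rates(self) -> np.ndarray:
        return np.concatenate([f.golgi_rates for f in self.per_field])

    def all_inhibition(self) -> np.ndarray:
        return np.concatenate([f.glomerular_inhibition for f in self.per_field])


def golgi_conversion(fields: list[FieldRates], cfg: NetworkConfig,
                     rng: np.random.Generator) -> GolgiEnsembleOutput:
    """Two-step Golgi conversion of field rate populations into glomerular inhibition.

    Step 1: per field, each of ``golgi_per_field`` cells forms
    ``golgi_basal_dendrites`` dendritic states (each the mean of
    ``mf_per_golgi_dendrite`` sampled local terminal rates) and a somatic rate
    (the mean of its own dendrites).  Step 2: each glomerulus of field *i*
    receives inhibition equal to the mean of a random 8-12 sample of somatic
    rates from the ensemble covering that field (fields i-1, i, i+1; truncated
    at strip ends).  E[inhibition] equals the mossy population mean on the
    normalized scale, because every stage is an unbiased mean.
    """
    n_fields = len(fields)
    if n_fields < 3:
        raise ValueError("golgi_conversion needs >= 3 fields (ensembles span 3-field rows)")
    norm = _normalized_field_rates(fields, cfg)

    n_golgi = cfg.golgi_per_field
    n_dend = cfg.golgi_basal_dendrites
    n_per_dend = cfg.mf_per_golgi_dendrite
    dendritic: list[np.ndarray] = []
    somata: list[np.ndarray] = []
    for x in norm:
        idx = rng.integers(0, x.size, size=(n_golgi, n_dend, n_per_dend))
        dmeans = x[idx].mean(axis=2)
        dendritic.append(dmeans)
        somata.append(dmeans.mean(axis=1))

    s_lo, s_hi = cfg.glomerulus_golgi_sample_low, cfg.glomerulus_golgi_sample_high
    out: list[GolgiFieldOutput] = []
    for i in range(n_fields):
        ens = np.concatenate(somata[max(0, i - 1):min(n_fields, i + 2)])
        n_glom = norm[i].size
        sizes = rng.integers(s_lo, s_hi + 1, size=n_glom)
        samples = ens[rng.integers(0, ens.size, size=(n_glom, s_hi))]
        mask = np.arange(s_hi)[None, :] < sizes[:, None]
        inhibition = (samples * mask).sum(axis=1) / sizes
        out.append(GolgiFieldOutput(field_index=i, dendritic_means=dendritic[i],
                                    golgi_rates=somata[i], ensemble_rates=ens,
                                    glomerular_inhibition=inhibition))
    return GolgiEnsembleOutput(per_field=out)


@dataclass
class GranuleWiring:
    """Fixed dendrite-to-glomerulus wiring, reusable across gain settings."""

    per_field_idx: list[np.ndarray]  # each (granule_per_field, granule_dendrites)


def draw_granule_wiring(fields: list[FieldRates], cfg: NetworkConfig,
                        rng: np.random.Generator) -> GranuleWiring:
    """Draw each granule cell's dendritic sample of distinct glomeruli."""
    n_cells, n_dend = cfg.granule_per_field, cfg.granule_dendrites
    wiring = []
    for f in fields:
        n_glom = f.rates_with_copies.size
        if n_glom < n_dend:
            raise ValueError("fewer glomeruli than granule dendrites in a field")
        idx = rng.integers(0, n_glom, size=(n_cells, n_dend))
        # enforce distinct glomeruli per cell by redrawing rows with repeats
        # (repeat probability ~ n_dend^2 / 2 n_glom, so redraw rounds are few)
        pairs = [(a, b) for a in range(n_dend) for b in range(a + 1, n_dend)]
        while True:
            bad = np.zeros(n_cells, dtype=bool)
            for a, b in pairs:
                bad |= idx[:, a] == idx[:, b]
            if not bad.any():
                break
            idx[bad] = rng.integers(0, n_glom, size=(int(bad.sum()), n_dend))
        wiring.append(idx)
    return GranuleWiring(per_field_idx=wiring)


@dataclass
class GranuleLayerOutput:
    """Per-field active-granule counts and normalized firing rates."""

    n_active: np.ndarray              # (n_fields,)
    active_rates: list[np.ndarray]    # normalized rates of active cells, per field
    granule_per_field: int
    gain: float

    @property
    def active_fraction(self) -> np.ndarray:
        return self.n_active / self.granule_per_field

    @property
    def mean_active_fraction(self) -> float:
        return float(self.active_fraction.mean())

    def pooled_rates(self) -> np.ndarray:
        return (np.concatenate(self.active_rates) if self.active_rates
                else np.empty(0))


def granule_activation(fields: list[FieldRates], inh: GolgiEnsembleOutput,
                       gain: float, cfg: NetworkConfig,
                       rng: np.random.Generator | None = None,
                       wiring: GranuleWiring | None = None) -> GranuleLayerOutput:
    """Apply the glomerular competition rule to every granule cell of a strip.

    A dendrite's input is dominant iff its normalized rate exceeds ``gain``
    times the spillover inhibition in its own glomerulus; a cell fires iff at
    least ``min_dominant_inputs`` dendrites are dominant, at a rate equal to
    the mean of its dominant input rates.
    """
    if gain < 0:
        raise ValueError("gain must be non-negative")
    if wiring is None:
        if rng is None:
            raise ValueError("provide either a wiring or an rng to draw one")
        wiring = draw_granule_wiring(fields, cfg, rng)
    norm = _normalized_field_rates(fields, cfg)
    n_active = np.empty(len(fields), dtype=int)
    active_rates: list[np.ndarray] = []
    for i, (x, fout, idx) in enumerate(zip(norm, inh.per_field, wiring.per_field_idx)):
        ex = x[idx]
        thr = gain * fout.glomerular_inhibition[idx]
        dominant = ex > thr
        n_dom = dominant.sum(axis=1)
        fires = n_dom >= cfg.min_dominant_inputs
        n_active[i] = int(fires.sum())
        with np.errstate(invalid="ignore"):
            rates = (ex * dominant).sum(axis=1)[fires] / n_dom[fires]
        active_rates.append(rates)
    return GranuleLayerOutput(n_active=n_active, active_rates=active_rates,
                              granule_per_field=cfg.granule_per_field, gain=gain)


class CalibrationError(RuntimeError):
    """Gain calibration could not bracket or converge on the target fraction."""


def calibrate_gain(fields: list[FieldRates], inh: GolgiEnsembleOutput,
                   target_fraction: float, cfg: NetworkConfig,
                   rng: np.random.Generator, rel_tol: float = 0.05,
                   max_iter: int = 80) -> float:
    """Bisect the global inhibition gain until the mean active fraction hits target.

    The granule wiring is drawn once and reused across evaluations, which makes
    the empirical active fraction exactly non-increasing in the gain (the
    dominance threshold scales monotonically); the search asserts this and
    raises :class:`CalibrationError` with diagnostics otherwise.
    """
    if not 0.0 < target_fraction < 1.0:
        raise ValueError("target_fraction must lie in (0, 1)")
    wiring = draw_granule_wiring(fields, cfg, rng)

    def fraction_at(g: float) -> float:
        return granule_activation(fields, inh, g, cfg,
                                  wiring=wiring).mean_active_fraction

    lo, f_lo = 0.0, fraction_at(0.0)
    if f_lo < target_fraction:
        raise CalibrationError(
            f"target {target_fraction} unreachable: active fraction at gain 0 is {f_lo:.4f}")
    hi, f_hi = 2.0, fraction_at(2.0)
    while f_hi > target_fraction:
        if hi > 1e6:
            raise CalibrationError("could not bracket the target: fraction "
                                   f"still {f_hi:.4f} at gain {hi}")
        hi *= 2.0
        f_hi = fraction_at(hi)
    history = [(lo, f_lo), (hi, f_hi)]
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = fraction_at(mid)
        history.append((mid, f_mid))
        if not f_hi - 1e-12 <= f_mid <= f_lo + 1e-12:
            raise CalibrationError(
                "active fraction is not monotone in gain; evaluations: "
                + ", ".join(f"({g:.4g}: {f:.4g})" for g, f in sorted(history)))
        if abs(f_mid - target_fraction) <= rel_tol * target_fraction:
            return mid
        if f_mid > target_fraction:
            lo, f_lo = mid, f_mid
        else:
            hi, f_hi = mid, f_mid
    raise CalibrationError(
        f"no convergence to {target_fraction} within {max_iter} bisections; "
        + "last evaluations: "
        + ", ".join(f"({g:.4g}: {f:.4g})" for g, f in history[-5:]))


@dataclass
class MicrofileAggregate:
    """Pooled granule output of one microfile (field j of every strip).

    The pooled rates of a microfile are the firing rates of the parallel
    fibers crossing the matching sector of the overlying microzone;
    ``weights`` carries the per-rate synaptic weight used when distal strips
    contribute fewer synapses.
    """

    microfile_index: int
    rates: np.ndarray
    weights: np.ndarray
    active_fraction: float

    @property
    def mean(self) -> float:
        if self.rates.size == 0:
            return float("nan")
        return float(np.average(self.rates, weights=self.weights))

    @property
    def sd(self) -> float:
        if self.rates.size < 2:
            return float("nan")
        m = self.mean
        return float(np.sqrt(np.average((self.rates - m) ** 2, weights=self.weights)))


def microfile_aggregate(outputs: list[GranuleLayerOutput], cfg: NetworkConfig,
                        strip_weights: np.ndarray | None = None
                        ) -> list[MicrofileAggregate]:
    """Aggregate field *j* of every strip into microfile *j*.

    ``strip_weights`` (one per strip, default all ones) scales both the
    contribution of each strip's rates and its share of the active-fraction
    estimate, implementing the distal parallel-fiber synapse taper.
    """
    if not outputs:
        raise ValueError("no strip outputs to aggregate")
    n_fields = {out.n_active.size for out in outputs}
    if len(n_fields) != 1:
        raise ValueError(f"ragged strip lengths: {sorted(n_fields)}")
    n = n_fields.pop()
    if strip_weights is None:
        strip_weights = np.ones(len(outputs))
    strip_weights = np.asarray(strip_weights, dtype=float)
    if strip_weights.size != len(outputs):
        raise ValueError("one weight per strip required")

    aggregates = []
    for j in range(n):
        rates = np.concatenate([out.active_rates[j] for out in outputs])
        weights = np.concatenate([np.full(out.active_rates[j].size, w)
                                  for out, w in zip(outputs, strip_weights)])
        frac = (sum(w * out.n_active[j] for out, w in zip(outputs, strip_weights))
                / (strip_weights.sum() * cfg.granule_per_field))
        aggregates.append(MicrofileAggregate(microfile_index=j, rates=rates,
                                             weights=weights,
                                             active_fraction=float(frac)))
    return aggregates
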