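"""Granular layer: Golgi conversion, granule activation, regulation, pooling."""

import numpy as np
import pytest
from scipy import stats

from simnet.config import NetworkConfig
from simnet.granular import (CalibrationError, calibrate_gain, draw_granule_wiring,
                             golgi_conversion, granule_activation,
                             microfile_aggregate)
from simnet.inputs import (FieldRates, RateDistributionSpec, normalize_rates,
                           simulate_strip)

UNIFORM = RateDistributionSpec(family="uniform", low=50, high=300)


def _constant_fields(n_fields, n_glom, rate_hz):
    return [FieldRates(i, np.full(n_glom, float(rate_hz))) for i in range(n_fields)]


class TestGolgiConversion:
    def test_constant_input_passes_through_exactly(self, small_cfg, rng):
        fields = _constant_fields(5, 120, 175.0)
        out = golgi_conversion(fields, small_cfg, rng)
        np.testing.assert_allclose(out.all_inhibition(), 0.5)
        np.testing.assert_allclose(out.all_golgi_rates(), 0.5)

    def test_needs_three_fields(self, small_cfg, rng):
        with pytest.raises(ValueError, match="3 fields"):
            golgi_conversion(_constant_fields(2, 120, 175.0), small_cfg, rng)

    def test_mean_linearly_coupled_and_chain_narrows(self, cfg, rng):
        """Each sampling stage narrows; the mean stays on the mossy mean."""
        _, fields = simulate_strip(UNIFORM, cfg, rng)
        out = golgi_conversion(fields, cfg, rng)
        mossy = normalize_rates(
            np.concatenate([f.rates_with_copies for f in fields]), 50, 300)
        inh = out.all_inhibition()
        # linear coupling: E[inhibition] == mossy population mean
        assert abs(inh.mean() - mossy.mean()) < 3 * mossy.std() / np.sqrt(600)
        assert inh.std() < out.all_golgi_rates().std() \
            < out.all_dendritic_means().std() < mossy.std()

    def test_ensemble_truncated_at_ends(self, small_cfg, rng):
        _, fields = simulate_strip(UNIFORM, small_cfg, rng)
        out = golgi_conversion(fields, small_cfg, rng)
        assert out.per_field[0].ensemble_rates.size == 2 * small_cfg.golgi_per_field
        assert out.per_field[1].ensemble_rates.size == 3 * small_cfg.golgi_per_field


class TestGranuleActivation:
    def test_zero_gain_activates_everyone(self, small_cfg, rng):
        _, fields = simulate_strip(UNIFORM, small_cfg, rng)
        inh = golgi_conversion(fields, small_cfg, rng)
        out = granule_activation(fields, inh, 0.0, small_cfg, rng=rng)
        assert out.mean_active_fraction == pytest.approx(1.0)

    def test_huge_gain_silences_everyone(self, small_cfg, rng):
        _, fields = simulate_strip(UNIFORM, small_cfg, rng)
        inh = golgi_conversion(fields, small_cfg, rng)
        out = granule_activation(fields, inh, 1e6, small_cfg, rng=rng)
        assert out.mean_active_fraction == 0.0

    def test_matches_explicit_loop_oracle(self, rng):
        """Vectorized competition rule equals a cell-by-cell reimplementation."""
        cfg = NetworkConfig(granule_per_field=10, fields_per_microstrip=100)
        fields = [FieldRates(i, rng.uniform(50, 300, 8)) for i in range(3)]
        inh = golgi_conversion(fields, cfg, rng)
        wiring = draw_granule_wiring(fields, cfg, np.random.default_rng(5))
        out = granule_activation(fields, inh, 1.1, cfg, wiring=wiring)
        gain = 1.1
        for i, f in enumerate(fields):
            ex = np.clip(normalize_rates(f.rates_with_copies, 50, 300), 0, 1)
            g = inh.per_field[i].glomerular_inhibition
            expected = []
            for cell in wiring.per_field_idx[i]:
                dom = [j for j in cell if ex[j] > gain * g[j]]
                if len(dom) >= cfg.min_dominant_inputs:
                    expected.append(np.mean([ex[j] for j in dom]))
            assert out.n_active[i] == len(expected)
            np.testing.assert_allclose(np.sort(out.active_rates[i]),
                                       np.sort(expected))

    def test_active_cells_sample_high_end(self, cfg, rng):
        """With inhibition engaged, active rates sit above the mossy mean."""
        _, fields = simulate_strip(UNIFORM, cfg, rng)
        inh = golgi_conversion(fields, cfg, rng)
        gain = calibrate_gain(fields, inh, 0.3, cfg, rng)
        out = granule_activation(fields, inh, gain, cfg, rng=rng)
        mossy_mean = normalize_rates(
            np.concatenate([f.rates_with_copies for f in fields]), 50, 300).mean()
        assert out.pooled_rates().mean() > mossy_mean
        # every active rate beats the gain-scaled inhibition floor of its field
        for i, rates in enumerate(out.active_rates):
            floor = gain * inh.per_field[i].glomerular_inhibition.min()
            assert (rates > floor).all()

    def test_wiring_distinct_glomeruli(self, small_cfg, rng):
        _, fields = simulate_strip(UNIFORM, small_cfg, rng)
        wiring = draw_granule_wiring(fields, small_cfg, rng)
        for idx in wiring.per_field_idx:
            assert all(np.unique(row).size == row.size for row in idx)

    def test_seeded_determinism(self, small_cfg):
        outs = []
        for _ in range(2):
            rng = np.random.default_rng(77)
            _, fields = simulate_strip(UNIFORM, small_cfg, rng)
            inh = golgi_conversion(fields, small_cfg, rng)
            outs.append(granule_activation(fields, inh, 1.0, small_cfg, rng=rng))
        np.testing.assert_array_equal(outs[0].n_active, outs[1].n_active)
        for a, b in zip(outs[0].active_rates, outs[1].active_rates):
            np.testing.assert_array_equal(a, b)


class TestCalibration:
    @pytest.mark.parametrize("target", [0.3, 0.05])
    def test_reaches_target(self, small_cfg, rng, target):
        _, fields = simulate_strip(UNIFORM, small_cfg, rng)
        inh = golgi_conversion(fields, small_cfg, rng)
        gain = calibrate_gain(fields, inh, target, small_cfg, rng)
        achieved = granule_activation(fields, inh, gain, small_cfg,
                                      rng=rng).mean_active_fraction
        assert abs(achieved - target) <= 0.1 * target + 2 * np.sqrt(
            target * (1 - target) / (small_cfg.granule_per_field
                                     * small_cfg.fields_per_microstrip))

    def test_unreachable_target_raises(self, small_cfg, rng):
        # every rate at the scale floor -> nothing can fire at any gain
        fields = _constant_fields(5, 150, 50.0)
        inh = golgi_conversion(fields, small_cfg, rng)
        with pytest.raises(CalibrationError, match="unreachable"):
            calibrate_gain(fields, inh, 0.5, small_cfg, rng)

    def test_constant_input_is_all_or_none(self, small_cfg, rng):
        """A degenerate constant-rate input flips from all to none at gain 1."""
        fields = _constant_fields(5, 150, 175.0)
        inh = golgi_conversion(fields, small_cfg, rng)
        below = granule_activation(fields, inh, 0.99, small_cfg, rng=rng)
        above = granule_activation(fields, inh, 1.01, small_cfg, rng=rng)
        assert below.mean_active_fraction == 1.0
        assert above.mean_active_fraction == 0.0
        with pytest.raises(CalibrationError):
            calibrate_gain(fields, inh, 0.5, small_cfg, rng, max_iter=20)


class TestMicrofileAggregate:
    def _outputs(self, cfg, rng, n_strips, gain=1.0):
        outs = []
        for i in range(n_strips):
            _, fields = simulate_strip(UNIFORM, cfg, rng, strip_index=i)
            inh = golgi_conversion(fields, cfg, rng)
            outs.append(granule_activation(fields, inh, gain, cfg, rng=rng))
        return outs

    def test_identical_strips_identical_microfiles(self, small_cfg):
        outs = [self._outputs(small_cfg, np.random.default_rng(9), 1)[0]
                for _ in range(3)]
        aggs = microfile_aggregate(outs, small_cfg)
        for a, out in zip(aggs, outs[0].active_rates):
            assert a.rates.size == 3 * out.size

    def test_ragged_strips_rejected(self, small_cfg, rng):
        outs = self._outputs(small_cfg, rng, 2)
        outs[1].n_active = outs[1].n_active[:-1]
        outs[1].active_rates = outs[1].active_rates[:-1]
        with pytest.raises(ValueError, match="ragged"):
            microfile_aggregate(outs, small_cfg)

    def test_aggregation_narrows_by_sqrt_n_strips(self, small_cfg, rng):
        """Microfile fractions scatter ~sqrt(n_strips) less than field fractions."""
        outs = self._outputs(small_cfg, rng, 9)
        aggs = microfile_aggregate(outs, small_cfg)
        field_sd = np.concatenate([o.active_fraction for o in outs]).std()
        file_sd = np.array([a.active_fraction for a in aggs]).std()
        assert file_sd < field_sd
        # independent strips: ratio should be near 1/3, generously bracketed
        assert file_sd < 0.7 * field_sd

    def test_strip_weights_shift_the_pool(self, small_cfg, rng):
        outs = self._outputs(small_cfg, rng, 2)
        w = np.array([1.0, 0.0])
        aggs = microfile_aggregate(outs, small_cfg, strip_weights=w)
        for a, o in zip(aggs, outs[0].active_rates):
            assert a.mean == pytest.approx(o.mean()) if o.size else True


def test_any_random_sample_codes_the_same_information(cfg, rng):
    """Two disjoint 500-cell samples of a strip's active rates agree (KS)."""
    _, fields = simulate_strip(UNIFORM, cfg, rng)
    inh = golgi_conversion(fields, cfg, rng)
    gain = calibrate_gain(fields, inh, 0.3, cfg, rng)
    pooled = granule_activation(fields, inh, gain, cfg, rng=rng).pooled_rates()
    pick = rng.permutation(pooled.size)[:1000]
    a, b = pooled[pick[:500]], pooled[pick[500:]]
    assert stats.ks_2samp(a, b).pvalue > 0.01
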