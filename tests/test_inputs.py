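"""Input synthesis: rate distributions, field derivation, sine profiles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from simnet.config import clusters_per_field
from simnet.inputs import (MicrostripRates, RateDistributionSpec,
                           derive_field_rates, draw_strip_rates,
                           normalize_rates, sine_wave_profile)


class TestRateDistributionSpec:
    def test_constant_draws_exact(self, rng):
        spec = RateDistributionSpec(family="constant", value=100.0)
        assert (spec.draw(5, rng) == 100.0).all()

    def test_uniform_mean(self, rng):
        spec = RateDistributionSpec(family="uniform", low=50, high=300)
        draws = spec.draw(10_000, rng)
        se = (300 - 50) / math.sqrt(12) / 100
        assert abs(draws.mean() - 175.0) < 3 * se
        assert draws.min() >= 50 and draws.max() <= 300

    def test_normal_tail_mass(self, rng):
        # mean 150 sd 25: [50, 300] covers (mean - 4sd, mean + 6sd) -> >=99%
        spec = RateDistributionSpec(family="normal", mean=150, sd=25,
                                    low=50, high=300)
        draws = spec.draw(10_000, rng)
        interior = ((draws > 50) & (draws < 300)).mean()
        assert interior >= 0.99

    def test_discontinuous_respects_gap(self, rng):
        spec = RateDistributionSpec(family="discontinuous", low=50, high=300,
                                    gap_low=140, gap_high=210)
        draws = spec.draw(5000, rng)
        assert not ((draws > 140) & (draws < 210)).any()
        assert abs(draws.mean() - 175.0) < 5.0  # symmetric gap keeps the mean

    def test_bimodal_modes(self, rng):
        spec = RateDistributionSpec(family="bimodal", mean=175, sd=10,
                                    separation=150, low=50, high=300)
        draws = spec.draw(5000, rng)
        assert ((draws < 140) | (draws > 210)).mean() > 0.98

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="unknown distribution family"):
            RateDistributionSpec(family="pareto")

    def test_missing_params_rejected(self):
        with pytest.raises(ValueError):
            RateDistributionSpec(family="normal", mean=100)

    def test_with_center_translates_shape(self, rng):
        spec = RateDistributionSpec(family="normal", mean=150, sd=25,
                                    low=50, high=250)
        shifted = spec.with_center(200.0)
        assert shifted.mean == 200.0 and shifted.low == 100.0 and shifted.high == 300.0
        a = spec.draw(4000, np.random.default_rng(7))
        b = shifted.draw(4000, np.random.default_rng(7))
        np.testing.assert_allclose(b, a + 50.0)


class TestStripAndFields:
    def test_draw_strip_reproducible(self, cfg):
        spec = RateDistributionSpec(family="uniform", low=50, high=300)
        a = draw_strip_rates(spec, 100, np.random.default_rng(3))
        b = draw_strip_rates(spec, 100, np.random.default_rng(3))
        np.testing.assert_array_equal(a.rates, b.rates)

    def test_field_rates_are_copies_of_strip_values(self, small_cfg, rng):
        spec = RateDistributionSpec(family="uniform", low=50, high=300)
        strip = draw_strip_rates(spec, 200, rng)
        fields = derive_field_rates(strip, small_cfg, rng)
        assert len(fields) == small_cfg.fields_per_microstrip
        pool = set(strip.rates.tolist())
        for f in fields:
            assert set(f.rates_with_copies.tolist()) <= pool

    def test_field_size_near_terminal_count(self, cfg, rng):
        spec = RateDistributionSpec(family="uniform", low=50, high=300)
        strip = draw_strip_rates(spec, 4000, rng)
        fields = derive_field_rates(strip, cfg, rng)
        sizes = np.array([f.rates_with_copies.size for f in fields])
        assert (np.abs(sizes - cfg.terminals_per_field)
                <= 0.2 * cfg.terminals_per_field).all()

    def test_constant_strip_gives_constant_fields(self, small_cfg, rng):
        strip = MicrostripRates(0, np.full(100, 120.0))
        for f in derive_field_rates(strip, small_cfg, rng):
            assert f.rates_with_copies.mean() == pytest.approx(120.0)

    def test_copies_do_not_move_the_mean(self, cfg, rng):
        """Duplicate signals leave per-field means near the raw sampling means."""
        spec = RateDistributionSpec(family="uniform", low=50, high=300)
        strip = draw_strip_rates(spec, 4000, rng)
        fields = derive_field_rates(strip, cfg, rng)
        means = np.array([f.rates_with_copies.mean() for f in fields])
        # field mean sampling SD ~ sigma/sqrt(distinct clusters)
        sd = strip.rates.std() / math.sqrt(clusters_per_field(cfg))
        assert (np.abs(means - strip.rates.mean()) < 4 * sd * 1.5).all()
        assert abs(means.mean() - strip.rates.mean()) < 4 * sd / math.sqrt(len(fields)) * 3


class TestSineProfile:
    BASE = RateDistributionSpec(family="normal", mean=175, sd=25, low=75, high=275)

    def test_full_wave_periodic(self):
        specs = sine_wave_profile(41, 1.0, 0.3, 175, 75, self.BASE)
        assert specs[0].center == pytest.approx(specs[40].center)
        centers = [s.center for s in specs]
        assert max(centers) <= 250.0 + 1e-9 and min(centers) >= 100.0 - 1e-9

    def test_quarter_wave_monotone_at_zero_phase(self):
        specs = sine_wave_profile(41, 0.25, 0.0, 175, 75, self.BASE)
        centers = np.array([s.center for s in specs])
        assert (np.diff(centers) > 0).all()

    def test_zero_amplitude_flat(self):
        specs = sine_wave_profile(10, 0.5, 1.0, 175, 0.0, self.BASE)
        assert all(s.center == pytest.approx(175.0) for s in specs)

    def test_too_few_strips_rejected(self):
        with pytest.raises(ValueError):
            sine_wave_profile(1, 0.5, 0.0, 175, 75, self.BASE)

    @settings(deadline=None, max_examples=30)
    @given(phase=st.floats(0, 2 * math.pi), wf=st.floats(0.05, 1.0))
    def test_centers_bounded_by_amplitude(self, phase, wf):
        specs = sine_wave_profile(21, wf, phase, 175, 60, self.BASE)
        for s in specs:
            assert 115.0 - 1e-6 <= s.center <= 235.0 + 1e-6


def test_normalize_round_trip():
    x = np.array([50.0, 175.0, 300.0])
    n = normalize_rates(x, 50.0, 300.0)
    np.testing.assert_allclose(n, [0.0, 0.5, 1.0])
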