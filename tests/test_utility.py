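"""Capacity arithmetic and expected utility of even/uneven allocations."""

import numpy as np
import pytest

from breadthdepth import (
    Allocation,
    CapacityParams,
    NoiseModel,
    PriorSpec,
    capacity,
    duality_convert,
    duality_invert,
    expected_max_std_normal,
    expected_utility_even,
    expected_utility_uneven,
    expected_utility_with_default,
    mc_expected_utility,
    per_option_capacity,
    pmax_pdf,
)

FAMILIES = ["gaussian", "uniform", "bimodal"]


class TestCapacity:
    def test_capacity_value(self):
        assert capacity(CapacityParams(T=0.1, sigma=1.0, sigma0=1.0)) == pytest.approx(0.1)
        assert capacity(CapacityParams(T=0.0)) == 0.0

    def test_capacity_scaling_invariance(self):
        # doubling sigma0^2 while halving T leaves C unchanged
        a = CapacityParams(T=1.0, sigma=1.3, sigma0=0.7)
        b = CapacityParams(T=0.5, sigma=1.3, sigma0=0.7 * np.sqrt(2))
        assert capacity(a) == pytest.approx(capacity(b))

    def test_per_option_capacities_sum_to_total(self):
        t = np.array([0.03, 0.05, 0.02])
        c = per_option_capacity(t, sigma=2.0, sigma0=0.5)
        assert c.sum() == pytest.approx(capacity(CapacityParams(0.1, 2.0, 0.5)))

    def test_invalid(self):
        with pytest.raises(ValueError):
            CapacityParams(T=-1.0)
        with pytest.raises(ValueError):
            CapacityParams(T=1.0, sigma=0.0)


class TestDuality:
    def test_even_thirds(self):
        # T/3 each at fixed sigma^2 <-> precision 1/(3 sigma^2) each at fixed T
        sigma = 1.4
        alloc = Allocation.even(3, 0.3)
        prec = duality_convert(alloc, sigma)
        assert np.allclose(prec.precisions, 1.0 / (3 * sigma**2))
        assert prec.common_time == pytest.approx(0.3)

    def test_single_active_option_gets_all_precision(self):
        # the total precision budget is 1/sigma^2; one active option takes it all
        sigma = 2.0
        prec = duality_convert(Allocation([0.2, 0.0]), sigma)
        assert prec.precisions[1] == 0.0
        assert prec.precisions[0] == pytest.approx(1.0 / sigma**2)
        assert prec.precisions.sum() == pytest.approx(1.0 / sigma**2)

    def test_round_trip_identity(self):
        t = np.array([0.07, 0.0, 0.01, 0.02])
        back = duality_invert(duality_convert(Allocation(t), 0.8), 0.8)
        assert np.allclose(back.times, t, atol=1e-15)

    def test_capacity_preserved(self):
        t = np.array([0.07, 0.03])
        sigma, sigma0 = 2.0, 0.5
        prec = duality_convert(Allocation(t), sigma)
        c_time = per_option_capacity(t, sigma, sigma0)
        c_prec = sigma0**2 * prec.common_time * prec.precisions
        assert np.allclose(c_time, c_prec)


class TestExpectedMax:
    def test_known_values(self):
        assert expected_max_std_normal(1) == 0.0
        assert expected_max_std_normal(2) == pytest.approx(1 / np.sqrt(np.pi), abs=1e-10)
        assert expected_max_std_normal(3) == pytest.approx(3 / (2 * np.sqrt(np.pi)), abs=1e-10)

    def test_strictly_increasing(self):
        vals = [expected_max_std_normal(M) for M in (1, 2, 3, 5, 10, 100, 1000, 10_000)]
        assert np.all(np.diff(vals) > 0)

    def test_invalid(self):
        with pytest.raises(ValueError):
            expected_max_std_normal(0)


class TestAllocation:
    def test_budget_consistency(self):
        with pytest.raises(ValueError):
            Allocation([0.05, 0.05], T=0.2)
        with pytest.raises(ValueError):
            Allocation([-0.1, 0.2])
        a = Allocation.even(2, 0.1, dims=5)
        assert a.active_count == 2 and a.T == pytest.approx(0.1)


class TestEvenUtility:
    def test_depth_limit_is_prior_mean(self, all_priors):
        for prior in all_priors.values():
            for C in (0.01, 1.0, 100.0):
                params = CapacityParams.for_prior(prior, C=C)
                assert expected_utility_even(prior, 1, params).value == prior.mu0

    def test_zero_capacity_is_prior_mean(self, all_priors):
        for prior in all_priors.values():
            params = CapacityParams.for_prior(prior, T=0.0)
            for M in (1, 2, 7, 100):
                assert expected_utility_even(prior, M, params).value == prior.mu0

    def test_gaussian_closed_form_value(self):
        # M=2, C=2: mu0 + (1/sqrt(2)) E[max of 2] = 0.5 + 1/sqrt(2 pi)... = 0.89894
        prior = PriorSpec.gaussian(0.5, 1.0)
        params = CapacityParams.from_capacity(2.0)
        expected = 0.5 + (1 / np.sqrt(2)) * (1 / np.sqrt(np.pi))
        assert expected_utility_even(prior, 2, params).value == \
            pytest.approx(expected, abs=1e-10)
        assert expected == pytest.approx(0.89894, abs=5e-6)

    def test_invalid_m(self, gaussian_prior):
        with pytest.raises(ValueError):
            expected_utility_even(gaussian_prior, 0, CapacityParams(1.0))

    @pytest.mark.parametrize("family", FAMILIES)
    def test_quadrature_matches_mc(self, all_priors, noise, family):
        prior = all_priors[family]
        params = CapacityParams.for_prior(prior, C=1.0)
        for M in (2, 6):
            quad = expected_utility_even(prior, M, params, noise).value
            mc = mc_expected_utility(prior, Allocation.even(M, params.T), noise,
                                     200_000, seed=M)
            assert abs(quad - mc.estimate.value) < 3.5 * mc.estimate.stderr

    def test_strictly_increasing_in_capacity(self, gaussian_prior):
        for M in (2, 5, 20):
            vals = [expected_utility_even(gaussian_prior, M,
                                          CapacityParams.from_capacity(C)).value
                    for C in np.geomspace(0.01, 100, 12)]
            assert np.all(np.diff(vals) > 0)

    @pytest.mark.parametrize("family", FAMILIES)
    def test_breadth_depth_shape(self, all_priors, family):
        # flat at M=1 (= mu0), interior maximum, decay back toward mu0 as M/C grows
        prior = all_priors[family]
        params = CapacityParams.for_prior(prior, C=0.1)
        ms = [1, 2, 3, 5, 8, 16, 64, 512, 4096]
        us = [expected_utility_even(prior, M, params).value for M in ms]
        assert us[0] == prior.mu0
        peak = int(np.argmax(us))
        assert 0 < peak < len(ms) - 1
        assert us[-1] - prior.mu0 < 0.3 * (max(us) - prior.mu0)

    def test_duality_invariance(self, gaussian_prior):
        # same capacity reached with different (T, sigma) gives the same utility
        u1 = expected_utility_even(gaussian_prior, 7, CapacityParams(T=0.4, sigma=2.0))
        u2 = expected_utility_even(gaussian_prior, 7, CapacityParams(T=0.1, sigma=1.0))
        assert u1.value == pytest.approx(u2.value, abs=1e-12)

    @pytest.mark.parametrize("family", FAMILIES)
    def test_pmax_density_normalized(self, all_priors, noise, family):
        prior = all_priors[family]
        for M, t in [(1, 0.5), (5, 0.02), (300, 1.0)]:
            sd = np.sqrt(prior.variance * t * t + t)
            y = prior.mu0 * t + sd * np.linspace(-9, 8 + np.sqrt(2 * np.log(max(M, 2))), 20001)
            assert np.trapezoid(pmax_pdf(prior, M, t, noise, y), y) == \
                pytest.approx(1.0, abs=1e-6)


class TestUnevenUtility:
    @pytest.mark.parametrize("family", FAMILIES)
    def test_reduces_to_even(self, all_priors, noise, family):
        prior = all_priors[family]
        params = CapacityParams.for_prior(prior, C=0.5)
        for M in (2, 5):
            even = expected_utility_even(prior, M, params, noise).value
            uneven = expected_utility_uneven(prior, Allocation.even(M, params.T), noise).value
            assert uneven == pytest.approx(even, abs=1e-8)

    @pytest.mark.parametrize("family", FAMILIES)
    def test_permutation_invariance(self, all_priors, noise, family):
        prior = all_priors[family]
        t = np.array([0.05, 0.0, 0.03, 0.02])
        u1 = expected_utility_uneven(prior, Allocation(t), noise).value
        u2 = expected_utility_uneven(prior, Allocation(t[::-1].copy()), noise).value
        assert u1 == pytest.approx(u2, abs=1e-9)

    def test_single_active_option(self, all_priors, noise):
        for prior in all_priors.values():
            alloc = Allocation([0.1, 0.0, 0.0])
            assert expected_utility_uneven(prior, alloc, noise).value == prior.mu0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            Allocation([0.0, 0.0])

    @pytest.mark.parametrize("family", FAMILIES)
    def test_uneven_matches_mc(self, all_priors, noise, family):
        prior = all_priors[family]
        t = np.array([0.06, 0.03, 0.01])
        quad = expected_utility_uneven(prior, Allocation(t), noise).value
        mc = mc_expected_utility(prior, Allocation(t), noise, 300_000, seed=7)
        assert abs(quad - mc.estimate.value) < 3.5 * mc.estimate.stderr


class TestDefaultOption:
    def test_m0_gives_prior_mean(self, all_priors):
        for prior in all_priors.values():
            params = CapacityParams.for_prior(prior, C=0.1)
            assert expected_utility_with_default(prior, 0, params).value == prior.mu0

    @pytest.mark.parametrize("family", FAMILIES)
    def test_dominates_no_default(self, all_priors, family):
        prior = all_priors[family]
        for C in (0.05, 1.0):
            params = CapacityParams.for_prior(prior, C=C)
            for M in (1, 3, 8):
                with_d = expected_utility_with_default(prior, M, params).value
                without = expected_utility_even(prior, M, params).value
                assert with_d >= without - 1e-12

    def test_small_capacity_argmax_still_five(self, gaussian_prior):
        params = CapacityParams.for_prior(gaussian_prior, C=0.05)
        us = [expected_utility_with_default(gaussian_prior, M, params).value
              for M in range(1, 25)]
        assert 1 + int(np.argmax(us)) == 5


def test_utility_never_below_prior_mean(all_priors):
    # choosing among unbiased estimates cannot fall below the prior mean
    rng = np.random.default_rng(3)
    for prior in all_priors.values():
        for _ in range(3):
            t = rng.dirichlet(np.ones(4)) * 0.2
            val = expected_utility_uneven(prior, Allocation(t), NoiseModel(1.0)).value
            assert val >= prior.mu0 - 1e-9
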