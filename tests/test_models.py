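"""Core model algebra: conversion profile, ODE oracle, constant relations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from doxrelease import (
    ConcentrationState,
    ExperimentCondition,
    RateConstants,
    conversion_profile,
    cooh_concentration,
    equilibrium_constant,
    normalized_binding_constant,
    ode_release_oracle,
    split_rate_constants,
)


class TestConversionProfile:
    def test_no_release_at_time_zero(self, neutral_310K_constants):
        assert conversion_profile(neutral_310K_constants, [0.0])[0] == 0.0

    def test_long_time_limit_is_equilibrium_conversion(self, neutral_310K_constants):
        # xi -> K/(1+K) = k1/(k1+k-1) = 0.0165/0.1695
        xi = conversion_profile(neutral_310K_constants, [1e4])[0]
        assert xi == pytest.approx(0.0165 / 0.1695, rel=1e-12)

    def test_five_hour_value_matches_closed_form(self, neutral_310K_constants):
        # frozen from exact evaluation of xi_inf(1 - e^{-0.1695*5})
        xi = conversion_profile(neutral_310K_constants, [5.0])[0]
        assert xi == pytest.approx(0.0556342224, abs=1e-8)

    def test_monotone_increasing_and_below_asymptote(self, neutral_310K_constants):
        t = np.linspace(0, 100, 300)
        xi = conversion_profile(neutral_310K_constants, t)
        assert np.all(np.diff(xi) > 0)
        assert np.all(xi < neutral_310K_constants.xi_inf)

    def test_negative_time_rejected(self, neutral_310K_constants):
        with pytest.raises(ValueError, match="times"):
            conversion_profile(neutral_310K_constants, [-1.0, 0.0])

    def test_zero_total_rate_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            conversion_profile(RateConstants(k1=0.0, k_minus1=0.0), [1.0])


class TestOdeOracle:
    def test_frozen_system_stays_constant(self):
        state = ode_release_oracle(RateConstants(k1=0.0, k_minus1=0.0), 1.0, [0, 5, 10])
        assert np.allclose(state.c_free, 0.0, atol=1e-12)
        assert np.allclose(state.c_bound, 1.0, atol=1e-12)

    def test_steady_state_detailed_balance(self, acidic_310K_constants):
        # k1 * c_bound = k_minus1 * c_free once dC/dt = 0
        state = ode_release_oracle(acidic_310K_constants, 2.0, [0.0, 500.0])
        k1, km1 = acidic_310K_constants.k1, acidic_310K_constants.k_minus1
        assert k1 * state.c_bound[-1] == pytest.approx(km1 * state.c_free[-1], rel=1e-6)

    def test_matches_closed_form_on_random_constants(self):
        rng = np.random.default_rng(2024)
        t = np.linspace(0.0, 60.0, 25)
        for _ in range(50):
            k1, km1 = 10 ** rng.uniform(-3, 0, size=2)
            rc = RateConstants(k1=k1, k_minus1=km1)
            state = ode_release_oracle(rc, 1.0, t)
            xi_closed = conversion_profile(rc, t)
            np.testing.assert_allclose(state.c_free, xi_closed, rtol=1e-8, atol=1e-10)

    def test_conservation_along_trajectory(self, neutral_310K_constants):
        c_max = 3.7e-4
        state = ode_release_oracle(neutral_310K_constants, c_max, np.linspace(0, 48, 49))
        # ConcentrationState enforces this at 1e-9 relative; re-check directly
        assert np.max(np.abs(state.c_free + state.c_bound - c_max)) <= 1e-9 * c_max

    def test_non_positive_c_max_rejected(self, neutral_310K_constants):
        with pytest.raises(ValueError, match="c_max"):
            ode_release_oracle(neutral_310K_constants, 0.0, [0, 1])


class TestConcentrationState:
    def test_conservation_violation_rejected(self):
        with pytest.raises(ValueError, match="conservation"):
            ConcentrationState(c_free=np.array([0.5]), c_bound=np.array([0.6]), c_max=1.0)


class TestEquilibriumConstant:
    @pytest.mark.parametrize(
        "xi_inf, expected",
        [(0.5, 1.0), (2.0 / 3.0, 2.0), (0.0165 / 0.1695, 0.0165 / 0.153)],
    )
    def test_known_values(self, xi_inf, expected):
        assert equilibrium_constant(xi_inf) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.5])
    def test_domain_enforced(self, bad):
        with pytest.raises(ValueError):
            equilibrium_constant(bad)

    def test_consistency_over_log_grid(self):
        # equilibrium_constant(K/(1+K)) returns K for K in 1e-3..1e3
        for K in np.logspace(-3, 3, 25):
            assert equilibrium_constant(K / (1 + K)) == pytest.approx(K, rel=1e-9)


class TestSplitRateConstants:
    def test_symmetric_split(self):
        rc = split_rate_constants(0.2, 1.0)
        assert (rc.k1, rc.k_minus1) == (pytest.approx(0.1), pytest.approx(0.1))

    def test_reproduces_published_pair(self):
        rc = split_rate_constants(0.1695, 0.0165 / 0.153)
        assert rc.k1 == pytest.approx(0.0165, rel=1e-12)
        assert rc.k_minus1 == pytest.approx(0.153, rel=1e-12)

    def test_zero_K_means_no_release(self):
        rc = split_rate_constants(0.3, 0.0)
        assert rc.k1 == 0.0
        assert rc.k_minus1 == pytest.approx(0.3)

    @given(
        k1=st.floats(1e-4, 10.0),
        km1=st.floats(1e-4, 10.0),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_split_recombine_round_trip(self, k1, km1):
        rc = split_rate_constants(k1 + km1, k1 / km1)
        assert rc.k1 == pytest.approx(k1, rel=1e-12)
        assert rc.k_minus1 == pytest.approx(km1, rel=1e-12)
        assert rc.k_total == pytest.approx(k1 + km1, rel=1e-12)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            split_rate_constants(-0.1, 1.0)
        with pytest.raises(ValueError):
            split_rate_constants(0.1, -1.0)


class TestNormalizedBindingConstant:
    def test_published_scale(self):
        # 0.153 1/h over 3.558e-3 mol/L of COOH
        assert normalized_binding_constant(0.153, 3.558e-3) == pytest.approx(43.0, abs=0.1)

    def test_zero_binding(self):
        assert normalized_binding_constant(0.0, 1e-3) == 0.0

    def test_inverse_proportional_to_cooh(self):
        assert normalized_binding_constant(0.1, 2e-3) == pytest.approx(
            normalized_binding_constant(0.1, 1e-3) / 2
        )

    def test_non_positive_cooh_rejected(self):
        with pytest.raises(ValueError):
            normalized_binding_constant(0.1, 0.0)


class TestCoohConcentration:
    def test_no_acrylic_acid_means_no_cooh(self):
        cond = ExperimentCondition(temperature=310, pH=7, x_aa=0.0, copolymer_conc=1e-2)
        assert cooh_concentration(cond) == 0.0

    def test_reference_composition(self, neutral_condition):
        # 10 g/L of 3.9 mol% AA copolymer, mean repeat mass ~109.6 g/mol
        assert cooh_concentration(neutral_condition) == pytest.approx(3.558e-3, rel=1e-3)

    def test_linear_in_concentration(self, neutral_condition):
        import dataclasses

        double = dataclasses.replace(neutral_condition, copolymer_conc=2e-2)
        assert cooh_concentration(double) == pytest.approx(
            2 * cooh_concentration(neutral_condition)
        )


class TestValidation:
    def test_condition_invariants(self):
        with pytest.raises(ValueError):
            ExperimentCondition(temperature=-1, pH=7, x_aa=0.1, copolymer_conc=1e-2)
        with pytest.raises(ValueError):
            ExperimentCondition(temperature=310, pH=15, x_aa=0.1, copolymer_conc=1e-2)
        with pytest.raises(ValueError):
            ExperimentCondition(temperature=310, pH=7, x_aa=1.2, copolymer_conc=1e-2)

    def test_rate_constant_invariants_and_derived(self):
        with pytest.raises(ValueError):
            RateConstants(k1=-0.1, k_minus1=0.1)
        rc = RateConstants(k1=0.2, k_minus1=0.1)
        assert rc.K == pytest.approx(2.0)
        assert rc.xi_inf == pytest.approx(2.0 / 3.0)
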