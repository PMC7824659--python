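"""Stationary-distribution and relaxation-diagnostics tests."""

import numpy as np
import pytest

from moverstayer import (
    Component,
    ComponentMixture,
    LinearCitySpec,
    ModelError,
    PopulationVector,
    RelocationModel,
    SpatialKernel,
    aggregate_kernel,
    equilibrium_approximation_error,
    evolve,
    linear_city_kernels,
    mixture_equilibrium,
    mixture_fixture,
    random_block_kernels,
    relaxation_diagnostics,
    stationary_distribution,
    transport_matrix,
)

from conftest import power_iteration_stationary, random_stochastic_matrix


class TestStationaryDistribution:
    def test_symmetric_two_zone_splits_evenly(self, swap_kernel):
        result = stationary_distribution(swap_kernel, total=100.0)
        np.testing.assert_allclose(result.x_eq.values, [50.0, 50.0], atol=1e-10)
        assert result.is_unique

    def test_three_zone_hub_matches_power_iteration_oracle(self):
        kernel = SpatialKernel([[0.0, 0.5, 0.5], [1.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        result = stationary_distribution(kernel, total=1.0)
        np.testing.assert_allclose(result.x_eq.values, [0.5, 0.25, 0.25], atol=1e-10)
        oracle = power_iteration_stationary(kernel.h)
        np.testing.assert_allclose(result.x_eq.values, oracle, atol=1e-10)

    @pytest.mark.parametrize("eps", [0.05, 0.5, 1.0])
    def test_equilibrium_independent_of_relocation_frequency(self, eps):
        rng = np.random.default_rng(2)
        kernel = SpatialKernel(random_stochastic_matrix(6, rng))
        base = stationary_distribution(kernel, total=1.0).x_eq.values
        scaled = stationary_distribution(RelocationModel(eps, kernel), total=1.0).x_eq.values
        np.testing.assert_allclose(scaled, base, atol=1e-8)

    def test_frozen_model_rejected(self, swap_kernel):
        with pytest.raises(ModelError):
            stationary_distribution(RelocationModel(0.0, swap_kernel))

    def test_non_stochastic_matrix_rejected(self):
        # the kernel type refuses non-stochastic rows, so bad matrices
        # cannot reach the eigen-solver in the first place
        with pytest.raises(ModelError, match="sums to"):
            SpatialKernel([[0.5, 0.4], [1.0, 0.0]])

    @pytest.mark.parametrize("n", [5, 20, 50])
    def test_eigenvector_matches_long_power_iteration_on_random_kernels(self, n):
        rng = np.random.default_rng(n)
        kernel = SpatialKernel(random_stochastic_matrix(n, rng))
        eig_based = stationary_distribution(kernel, total=1.0).x_eq.values
        oracle = power_iteration_stationary(kernel.h, steps=10_000)
        np.testing.assert_allclose(eig_based, oracle, atol=1e-8)

    def test_reducible_kernel_flagged_not_rejected(self):
        h1, _ = random_block_kernels(9, tuple(range(3, 7)), seed=4)
        result = stationary_distribution(h1, total=1.0)
        assert not result.is_unique
        support = result.x_eq.values > 1e-12
        np.testing.assert_array_equal(np.flatnonzero(support), np.arange(2, 6))


class TestMixtureEquilibrium:
    def test_shared_kernel_components_are_alpha_scaled(self, swap_kernel):
        mix = ComponentMixture(
            (Component(0.3, 0.05, swap_kernel), Component(0.7, 0.5, swap_kernel))
        )
        result = mixture_equilibrium(mix, total=100.0)
        np.testing.assert_allclose(result.per_component[0].values, [15.0, 15.0], atol=1e-8)
        np.testing.assert_allclose(result.per_component[1].values, [35.0, 35.0], atol=1e-8)
        np.testing.assert_allclose(result.x_eq.values, [50.0, 50.0], atol=1e-8)

    def test_single_component_mixture_reduces_to_kernel_equilibrium(self):
        kernel = SpatialKernel([[0.0, 0.5, 0.5], [1.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        mix = ComponentMixture((Component(1.0, 0.3, kernel),))
        result = mixture_equilibrium(mix, total=1.0)
        np.testing.assert_allclose(result.x_eq.values, [0.5, 0.25, 0.25], atol=1e-10)

    def test_opposite_absorbing_destinations_split_mass(self):
        # each kernel funnels every mover into one zone: unit-mass equilibria
        to_first = SpatialKernel(np.tile([1.0, 0.0], (2, 1)))
        to_second = SpatialKernel(np.tile([0.0, 1.0], (2, 1)))
        mix = ComponentMixture(
            (Component(0.5, 0.4, to_first), Component(0.5, 0.4, to_second))
        )
        result = mixture_equilibrium(mix, total=1.0)
        np.testing.assert_allclose(result.x_eq.values, [0.5, 0.5], atol=1e-10)

    def test_shared_kernel_mixture_trajectory_converges_to_alpha_weighted_equilibrium(self):
        mix = mixture_fixture("shared", alpha=0.3, epsilons=(0.2, 0.6), n_zones=21, center=11)
        x0 = np.zeros(21)
        x0[0] = 1.0
        trace = evolve(PopulationVector(x0), mix, 120)
        result = mixture_equilibrium(mix, total=1.0)
        for k in range(2):
            np.testing.assert_allclose(
                trace.component_states[k, -1], result.per_component[k].values, atol=1e-6
            )


class TestAggregateKernel:
    def test_identical_kernels_aggregate_to_themselves(self, swap_kernel):
        mix = ComponentMixture(
            (Component(0.4, 0.1, swap_kernel), Component(0.6, 0.9, swap_kernel))
        )
        np.testing.assert_allclose(aggregate_kernel(mix).h, swap_kernel.h)

    def test_convex_combination_of_permutations(self, swap_kernel):
        stay = SpatialKernel(np.eye(2))
        mix = ComponentMixture((Component(0.5, 0.1, stay), Component(0.5, 0.1, swap_kernel)))
        np.testing.assert_allclose(aggregate_kernel(mix).h, [[0.5, 0.5], [0.5, 0.5]])

    def test_shared_kernel_approximation_error_vanishes(self, swap_kernel):
        mix = ComponentMixture(
            (Component(0.2, 0.1, swap_kernel), Component(0.8, 0.7, swap_kernel))
        )
        assert equilibrium_approximation_error(mix) < 1e-10

    def test_opposed_linear_city_aggregate_is_adequate(self):
        mix = mixture_fixture("opposed", alpha=0.5, epsilons=(0.2, 0.2))
        assert equilibrium_approximation_error(mix) < 0.1

    def test_absorbing_destination_error_matches_brute_force(self):
        to_first = SpatialKernel(np.tile([1.0, 0.0, 0.0], (3, 1)))
        to_third = SpatialKernel(np.tile([0.0, 0.0, 1.0], (3, 1)))
        mix = ComponentMixture(
            (Component(0.5, 0.4, to_first), Component(0.5, 0.4, to_third))
        )
        true_eq = 0.5 * power_iteration_stationary(to_first.h, 200) + \
            0.5 * power_iteration_stationary(to_third.h, 200)
        approx_eq = power_iteration_stationary(aggregate_kernel(mix).h, 10_000)
        expected = np.abs(true_eq - approx_eq).sum()
        assert equilibrium_approximation_error(mix) == pytest.approx(expected, abs=1e-8)


class TestTransportMatrix:
    def test_frozen_population_has_zero_transport(self, swap_kernel):
        np.testing.assert_array_equal(
            transport_matrix(RelocationModel(0.0, swap_kernel)), np.zeros((2, 2))
        )

    def test_two_zone_form(self, swap_kernel):
        np.testing.assert_allclose(
            transport_matrix(RelocationModel(0.1, swap_kernel)),
            [[-0.1, 0.1], [0.1, -0.1]],
            atol=1e-15,
        )

    def test_rows_sum_to_zero_for_random_models(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            kernel = SpatialKernel(random_stochastic_matrix(7, rng))
            l = transport_matrix(RelocationModel(float(rng.uniform(0, 1)), kernel))
            np.testing.assert_allclose(l.sum(axis=1), 0.0, atol=1e-12)


class TestRelaxationDiagnostics:
    def test_two_zone_rate_to_force_ratio_is_twice_the_frequency(self, swap_kernel):
        # zero-sum vectors are eigenvectors of the symmetric chain: |Q|/|U| = 2e
        eps = 0.1
        model = RelocationModel(eps, swap_kernel)
        trace = evolve(PopulationVector([100.0, 0.0]), model, 30)
        result = stationary_distribution(model, total=100.0)
        est = relaxation_diagnostics(trace, result, model)
        assert est.near_equilibrium_ratio == pytest.approx(2 * eps, abs=1e-9)
        assert est.fitted_slope == pytest.approx(np.log(1 - 2 * eps), abs=1e-9)
        assert est.fitted_slope < 0

    def test_linear_city_fitted_slope_matches_spectrum(self):
        h1, _ = linear_city_kernels(LinearCitySpec())
        model = RelocationModel(0.2, h1)
        x0 = np.zeros(99)
        x0[0] = 1000.0
        trace = evolve(PopulationVector(x0), model, 60)
        result = stationary_distribution(model, total=1000.0)
        est = relaxation_diagnostics(trace, result, model)
        assert est.predicted_slope == pytest.approx(np.log(0.8), abs=1e-9)
        assert abs(est.fitted_slope - est.predicted_slope) < 0.02 * abs(est.predicted_slope)

    def test_driving_force_eventually_monotone(self):
        rng = np.random.default_rng(13)
        kernel = SpatialKernel(random_stochastic_matrix(8, rng))
        model = RelocationModel(0.5, kernel)
        x0 = rng.random(8) * 10
        trace = evolve(PopulationVector(x0), model, 40)
        result = stationary_distribution(model, total=float(x0.sum()))
        u_norm = np.linalg.norm(trace.states - result.x_eq.values, axis=1)
        tail = u_norm[20:]
        assert np.all(np.diff(tail[tail > 1e-14]) <= 0)

    def test_identity_model_rejected_by_primitivity(self, swap_kernel):
        model = RelocationModel(0.0, swap_kernel)
        trace = evolve(PopulationVector([60.0, 40.0]), model, 10)
        fake_eq = stationary_distribution(swap_kernel, total=100.0)
        with pytest.raises(ModelError, match="primitive"):
            relaxation_diagnostics(trace, fake_eq, model)

    def test_already_at_equilibrium_rejected(self, swap_kernel):
        model = RelocationModel(0.2, swap_kernel)
        trace = evolve(PopulationVector([50.0, 50.0]), model, 10)
        result = stationary_distribution(model, total=100.0)
        with pytest.raises(ModelError, match="equilibrium"):
            relaxation_diagnostics(trace, result, model)

    def test_per_component_diagnostics_use_component_spectrum(self, swap_kernel):
        mix = ComponentMixture(
            (Component(0.5, 0.1, swap_kernel), Component(0.5, 0.4, swap_kernel))
        )
        trace = evolve(PopulationVector([80.0, 20.0]), mix, 30)
        result = mixture_equilibrium(mix, total=100.0)
        est0 = relaxation_diagnostics(trace, result, mix, component=0)
        est1 = relaxation_diagnostics(trace, result, mix, component=1)
        assert est0.predicted_slope == pytest.approx(np.log(1 - 2 * 0.1), abs=1e-9)
        assert est1.predicted_slope == pytest.approx(np.log(1 - 2 * 0.4), abs=1e-9)
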