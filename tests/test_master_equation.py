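"""Master equation on the count lattice: lattice, fluxes, closed forms, moments."""

import math

import numpy as np
import pytest

import cohortme as cm
from cohortme.master_eq import (
    LatticeDistribution,
    LatticeSizeError,
    MasterEquationSystem,
    TransitionEvent,
    empirical_moments_from_distribution,
    events_from_generator,
)
from cohortme.io import random_model


@pytest.fixture(scope="module")
def sys4_small(example_cfg):
    return MasterEquationSystem(example_cfg.generator(), 10)


class TestLattice:
    def test_two_state_colex_order(self):
        lat = cm.enumerate_lattice(2, 3)
        np.testing.assert_array_equal(lat, [[3, 0], [2, 1], [1, 2], [0, 3]])

    @pytest.mark.parametrize("s, n0, size", [(3, 2, 6), (4, 10, 286), (2, 50, 51)])
    def test_sizes_match_stars_and_bars(self, s, n0, size):
        lat = cm.enumerate_lattice(s, n0)
        assert lat.shape == (size, s)
        assert size == math.comb(n0 + s - 1, s - 1)
        assert np.all(lat.sum(axis=1) == n0)
        assert len({tuple(r) for r in lat.tolist()}) == size

    def test_cap_exceeded_raises(self):
        with pytest.raises(LatticeSizeError, match="cap"):
            cm.enumerate_lattice(4, 10, cap=100)


class TestPropensity:
    def test_scales_with_source_occupancy(self, example_cfg):
        states = example_cfg.state_space()
        n = cm.StateConfiguration(states=states, counts=np.array([10000, 0, 0, 0]))
        ev = TransitionEvent(source=0, target=1, rate=0.05)
        assert cm.propensity(n, ev) == 500.0

    def test_empty_source_gives_zero(self, example_cfg):
        states = example_cfg.state_space()
        n = cm.StateConfiguration(states=states, counts=np.array([0, 5, 0, 5]))
        assert cm.propensity(n, TransitionEvent(0, 1, 0.05)) == 0.0

    def test_small_hand_computation(self):
        states = cm.StateSpace(["A", "B"])
        n = cm.StateConfiguration(states=states, counts=np.array([3, 1]))
        assert cm.propensity(n, TransitionEvent(source=1, target=0, rate=2.0)) == 2.0

    def test_change_vector(self):
        ev = TransitionEvent(source=0, target=2, rate=1.0)
        np.testing.assert_array_equal(ev.change(3), [-1, 0, 1])


class TestMasterRHS:
    def test_concentrated_mass_pure_outflux(self, sys4_small):
        d = LatticeDistribution.degenerate(sys4_small, (10, 0, 0, 0))
        rhs = cm.master_rhs(d)
        i = sys4_small.config_index((10, 0, 0, 0))
        assert rhs[i] == pytest.approx(-10 * 0.061)
        assert abs(rhs.sum()) < 1e-12

    def test_flux_conserves_probability_for_random_mass(self, sys4_small):
        rng = np.random.default_rng(0)
        mass = rng.dirichlet(np.ones(sys4_small.lattice.shape[0]))
        d = LatticeDistribution(system=sys4_small, mass=mass)
        assert abs(cm.master_rhs(d).sum()) < 1e-12

    def test_single_individual_bookkeeping(self):
        states = cm.StateSpace(["A", "B"])
        Q = cm.build_generator(states, {("A", "B"): 0.7})
        system = MasterEquationSystem(Q, 1)
        d = LatticeDistribution.degenerate(system, (1, 0))
        rhs = cm.master_rhs(d)
        assert rhs[system.config_index((0, 1))] == pytest.approx(0.7)


class TestBruteForceOracle:
    def test_zero_generator_leaves_distribution_unchanged(self):
        states = cm.StateSpace(["A", "B"])
        Q = cm.build_generator(states, {})
        system = MasterEquationSystem(Q, 3)
        rng = np.random.default_rng(1)
        mass = rng.dirichlet(np.ones(4))
        d0 = LatticeDistribution(system=system, mass=mass)
        sols = cm.solve_master_bruteforce(d0, cm.TimeGrid.from_times([0, 1, 5]))
        for s in sols:
            np.testing.assert_allclose(s.mass, mass, atol=1e-9)

    def test_single_individual_exponential_survival(self):
        lam = 0.8
        states = cm.StateSpace(["A", "B"])
        Q = cm.build_generator(states, {("A", "B"): lam})
        system = MasterEquationSystem(Q, 1)
        d0 = LatticeDistribution.degenerate(system, (1, 0))
        grid = cm.TimeGrid.from_times([0.0, 0.5, 1.0, 2.0])
        sols = cm.solve_master_bruteforce(d0, grid)
        for t, sol in zip(grid.times, sols):
            assert sol.probability((1, 0)) == pytest.approx(np.exp(-lam * t),
                                                            abs=1e-9)

    def test_oracle_matches_multinomial_on_example_lattice(self, sys4_small):
        """Numerical integration of the flux balance reproduces the closed form."""
        d0 = LatticeDistribution.degenerate(sys4_small, (10, 0, 0, 0))
        grid = cm.TimeGrid.from_times([0.0, 1.0, 5.0, 10.0])
        sols = cm.solve_master_bruteforce(d0, grid)
        for t, sol in zip(grid.times, sols):
            ex = cm.exact_distribution(sys4_small, t)
            assert np.max(np.abs(sol.mass - ex.mass)) < 1e-8


class TestExactProbability:
    def test_time_zero_is_degenerate(self, sys4_small):
        states = sys4_small.generator.states
        start = cm.StateConfiguration(states=states, counts=np.array([10, 0, 0, 0]))
        assert cm.exact_probability(sys4_small, start, 0.0) == pytest.approx(1.0)
        other = cm.StateConfiguration(states=states, counts=np.array([9, 1, 0, 0]))
        assert cm.exact_probability(sys4_small, other, 0.0) == 0.0

    def test_binomial_special_case(self):
        states = cm.StateSpace(["A", "B"])
        Q = cm.build_generator(states, {("A", "B"): 0.4})
        system = MasterEquationSystem(Q, 3)
        t = 1.7
        p = 1 - np.exp(-0.4 * t)  # B_12(t)
        n = cm.StateConfiguration(states=states, counts=np.array([1, 2]))
        assert cm.exact_probability(system, n, t) == pytest.approx(
            3 * p**2 * (1 - p), rel=1e-12
        )

    def test_normalizes_over_lattice(self, sys4_small):
        for t in (0.5, 3.0):
            d = cm.exact_distribution(sys4_small, t)
            assert abs(d.mass.sum() - 1.0) < 1e-9

    def test_wrong_total_raises(self, sys4_small):
        states = sys4_small.generator.states
        n = cm.StateConfiguration(states=states, counts=np.array([5, 0, 0, 0]))
        with pytest.raises(cm.ModelValidationError):
            cm.exact_probability(sys4_small, n, 1.0)

    def test_large_cohort_no_overflow(self, example_cfg):
        """Log-space evaluation keeps n0 = 10000 masses finite."""
        system = MasterEquationSystem(example_cfg.generator(), 10000)
        states = system.generator.states
        b = cm.propagator(system.generator, 1.0).probs[0]
        mode = np.floor(10000 * b).astype(int)
        mode[0] += 10000 - mode.sum()
        n = cm.StateConfiguration(states=states, counts=mode)
        p = cm.exact_probability(system, n, 1.0)
        assert 0 < p < 1


class TestArbitraryInitial:
    def test_degenerate_reduction(self, sys4_small):
        d0 = LatticeDistribution.degenerate(sys4_small, (10, 0, 0, 0))
        states = sys4_small.generator.states
        t = 2.0
        ex = cm.exact_distribution(sys4_small, t)
        ar = cm.exact_distribution_arbitrary(sys4_small, d0, t)
        assert np.max(np.abs(ex.mass - ar.mass)) < 1e-12

    def test_time_zero_returns_initial_mass(self):
        states = cm.StateSpace(["A", "B", "C"])
        Q = cm.build_generator(states, {("A", "B"): 0.2, ("B", "C"): 0.5})
        system = MasterEquationSystem(Q, 4)
        d0 = LatticeDistribution.from_points(
            system, [((2, 2, 0), 0.3), ((4, 0, 0), 0.7)]
        )
        n = cm.StateConfiguration(states=states, counts=np.array([2, 2, 0]))
        assert cm.exact_probability_arbitrary(system, d0, n, 0.0) == 0.3

    def test_two_independent_individuals(self):
        """Start (1,1) with pure decay: both in B with prob 1 - e^{-lam t}."""
        lam = 0.6
        states = cm.StateSpace(["A", "B"])
        Q = cm.build_generator(states, {("A", "B"): lam})
        system = MasterEquationSystem(Q, 2)
        d0 = LatticeDistribution.degenerate(system, (1, 1))
        t = 1.3
        n = cm.StateConfiguration(states=states, counts=np.array([0, 2]))
        assert cm.exact_probability_arbitrary(system, d0, n, t) == pytest.approx(
            1 - np.exp(-lam * t), rel=1e-10
        )

    def test_matches_oracle_for_mixture(self):
        cfg = random_model(3, seed=11, rate_scale=0.4, n0=5)
        system = MasterEquationSystem(cfg.generator(), 5)
        d0 = LatticeDistribution.from_points(
            system, [((3, 2, 0), 0.4), ((5, 0, 0), 0.6)]
        )
        grid = cm.TimeGrid.from_times([0.0, 0.5, 2.0])
        sols = cm.solve_master_bruteforce(d0, grid)
        for t, sol in zip(grid.times, sols):
            ar = cm.exact_distribution_arbitrary(system, d0, t)
            assert np.max(np.abs(sol.mass - ar.mass)) < 1e-7


class TestPGF:
    def test_normalization_at_ones(self, sys4_small):
        assert cm.pgf_evaluate(sys4_small, np.ones(4), 3.0) == pytest.approx(1.0)

    def test_time_zero_is_x1_power(self, sys4_small):
        x = np.array([0.5, 0.2, 0.9, 0.1])
        assert cm.pgf_evaluate(sys4_small, x, 0.0) == pytest.approx(0.5**10)

    def test_two_state_survival_probability(self):
        states = cm.StateSpace(["A", "B"])
        Q = cm.build_generator(states, {("A", "B"): 0.4})
        system = MasterEquationSystem(Q, 2)
        t = 2.0
        p = 1 - np.exp(-0.4 * t)
        assert cm.pgf_evaluate(system, [1.0, 0.0], t) == pytest.approx((1 - p) ** 2)

    def test_matches_lattice_sum_definition(self, sys4_small):
        """G(x,t) equals sum_n x^n P(n,t) computed from the closed form."""
        t = 1.5
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 1, size=4)
        d = cm.exact_distribution(sys4_small, t)
        direct = float(np.sum(d.mass * np.prod(x ** sys4_small.lattice, axis=1)))
        assert cm.pgf_evaluate(sys4_small, x, t) == pytest.approx(direct, abs=1e-9)

    def test_derivative_at_ones_gives_mean(self, sys4_small):
        """Finite-difference dG/dx_i at x = 1 equals the mean count."""
        t, h = 2.0, 1e-6
        grid = cm.TimeGrid.from_times([t])
        grid0 = cm.TimeGrid(t0=0.0, times=np.array([t]))
        mom = cm.analytic_moments(sys4_small, grid0)
        for i in range(4):
            x = np.ones(4)
            x[i] += h
            d = (cm.pgf_evaluate(sys4_small, x, t) - 1.0) / h
            assert abs(d - mom.mean[0, i]) < 1e-4 * sys4_small.n0


class TestAnalyticMoments:
    def test_time_zero_moments(self, sys4_small):
        grid = cm.TimeGrid.uniform(0.0, 1.0, 3)
        mom = cm.analytic_moments(sys4_small, grid)
        np.testing.assert_allclose(mom.mean[0], [10, 0, 0, 0])
        np.testing.assert_allclose(mom.variance[0], 0.0, atol=1e-12)

    def test_two_state_closed_form_values(self):
        states = cm.StateSpace(["A", "B"])
        Q = cm.build_generator(states, {("A", "B"): 0.1})
        system = MasterEquationSystem(Q, 10000)
        grid = cm.TimeGrid.from_times([10.0])
        grid = cm.TimeGrid(t0=0.0, times=np.array([10.0]))
        mom = cm.analytic_moments(system, grid)
        e = np.exp(-1.0)
        np.testing.assert_allclose(mom.mean[0], [10000 * e, 10000 * (1 - e)],
                                   rtol=1e-12)
        assert mom.variance[0, 0] == pytest.approx(10000 * e * (1 - e), rel=1e-12)

    def test_mean_matches_ode_trajectory(self, example_cfg):
        cfg = example_cfg
        system = MasterEquationSystem(cfg.generator(), 10000)
        grid = cfg.grid()
        mom = cm.analytic_moments(system, grid)
        N0 = cm.OccupancyVector(states=cfg.state_space(),
                                values=np.array([10000.0, 0, 0, 0]))
        ode = cm.ode_mean_trajectory(N0, cfg.generator(), grid).as_array()
        assert np.max(np.abs(mom.mean - ode)) < 1e-8 * 10000
        np.testing.assert_allclose(mom.mean.sum(axis=1), 10000, atol=1e-9 * 10000)

    def test_lattice_summed_moments_match_formulas(self, sys4_small):
        grid = cm.TimeGrid(t0=0.0, times=np.array([0.5, 2.0, 6.0]))
        mom = cm.analytic_moments(sys4_small, grid)
        dists = [cm.exact_distribution(sys4_small, t) for t in grid.times]
        emp = empirical_moments_from_distribution(dists, grid)
        assert np.max(np.abs(mom.mean - emp.mean)) < 1e-7
        assert np.max(np.abs(mom.variance - emp.variance)) < 1e-7

    def test_variance_bounded_by_binomial_maximum(self, sys4_small):
        grid = cm.TimeGrid.uniform(0.0, 0.5, 40)
        mom = cm.analytic_moments(sys4_small, grid)
        assert np.all(mom.variance <= sys4_small.n0 / 4 + 1e-9)
        assert np.all(mom.variance >= -1e-12)

    def test_absorbing_limit(self, example_cfg):
        """All mass drains into the absorbing state: mean -> n0, variance -> 0."""
        Q = example_cfg.generator()
        system = MasterEquationSystem(Q, 10000)
        t_end = min(500.0, 10 / np.max(np.abs(np.diag(Q.rates)))
                    * np.log(10000 * 1e6))
        grid = cm.TimeGrid(t0=0.0, times=np.array([t_end]))
        mom = cm.analytic_moments(system, grid)
        assert mom.mean[0, 3] >= 0.99 * 10000
        assert mom.variance[0, 3] <= 0.01 * 10000
        # and far beyond that horizon the limit is essentially exact
        far = cm.analytic_moments(system, cm.TimeGrid(t0=0.0, times=np.array([500.0])))
        assert far.mean[0, 3] == pytest.approx(10000, abs=1e-6)
        assert far.variance[0, 3] < 1e-6


class TestArbitraryMoments:
    def test_degenerate_reduction(self, sys4_small):
        grid = cm.TimeGrid.uniform(0.0, 1.0, 5)
        d0 = LatticeDistribution.degenerate(sys4_small, (10, 0, 0, 0))
        a = cm.analytic_moments_arbitrary(sys4_small, d0, grid)
        b = cm.analytic_moments(sys4_small, grid)
        np.testing.assert_allclose(a.mean, b.mean, atol=1e-10)
        np.testing.assert_allclose(a.variance, b.variance, atol=1e-10)

    def test_zero_generator_keeps_initial_spread(self):
        """c = 0: mean stays at E[n0], variance is the pure initial spread."""
        states = cm.StateSpace(["A", "B"])
        Q = cm.build_generator(states, {})
        system = MasterEquationSystem(Q, 2)
        d0 = LatticeDistribution.from_points(system, [((2, 0), 0.5), ((0, 2), 0.5)])
        grid = cm.TimeGrid.uniform(0.0, 1.0, 3)
        mom = cm.analytic_moments_arbitrary(system, d0, grid)
        np.testing.assert_allclose(mom.mean, 1.0, atol=1e-12)
        # N_1 is 2 or 0 with probability 1/2 each: Var = E[N^2] - 1 = 1
        np.testing.assert_allclose(mom.variance, 1.0, atol=1e-12)

    def test_matches_oracle_moments_for_mixture(self):
        cfg = random_model(3, seed=23, rate_scale=0.5, n0=5)
        system = MasterEquationSystem(cfg.generator(), 5)
        d0 = LatticeDistribution.from_points(
            system, [((2, 3, 0), 0.25), ((5, 0, 0), 0.75)]
        )
        grid = cm.TimeGrid.from_times([0.0, 1.0, 4.0])
        sols = cm.solve_master_bruteforce(d0, grid)
        emp = empirical_moments_from_distribution(sols, grid)
        mom = cm.analytic_moments_arbitrary(system, d0, grid)
        assert np.max(np.abs(mom.mean - emp.mean)) < 1e-7
        assert np.max(np.abs(mom.variance - emp.variance)) < 1e-7
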