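"""Gate constants, the cascade recursion, and dominance of the bound."""

import numpy as np
import pytest
from scipy.integrate import quad

import rxnpaths as rp
from rxnpaths.gating import (
    cascade_chains,
    cascade_upper_bound,
    gate_constant,
    ungated_chain,
    verify_bound,
)
from rxnpaths.paths import Path, PathChain, path_chain_solve, path_chain_solve_ode

from conftest import random_chain


class TestGateConstant:
    def test_single_gate_closed_form(self):
        """C_2 = C * (beta/alpha_1) * (1 - e^{-alpha_1 dt})."""
        chain = PathChain(
            path=Path(((0,), (1,), (2,)), (0, 0)), C=0.9,
            alphas=(1.3, 0.8, 0.5), betas=(0.7, 0.4),
        )
        dt = 3.0
        expected = 0.9 * (0.7 / 1.3) * (1 - np.exp(-1.3 * dt))
        assert gate_constant(chain, 2, dt) == pytest.approx(expected, abs=1e-14)

    def test_worked_birth_death_value(self, example_chain):
        """Level-2 gate of the worked chain: (1/1.2)(1 - e^{-12})."""
        c2 = gate_constant(example_chain, 2, 10.0)
        assert c2 == pytest.approx((1 / 1.2) * (1 - np.exp(-12.0)), abs=1e-12)
        assert c2 == pytest.approx(0.8333, abs=1e-4)

    def test_matches_quadrature_oracle(self, example_chain):
        """Oracle: numerically integrate the upstream state's probability."""
        polys, _ = path_chain_solve(example_chain)
        for j, dt in ((2, 10.0), (3, 5.0), (4, 2.0)):
            ref, _ = quad(polys[j - 2], 0, dt, epsabs=1e-14, epsrel=1e-12)
            beta = example_chain.betas[j - 2]
            assert gate_constant(example_chain, j, dt) == pytest.approx(
                beta * ref, abs=1e-10
            )

    def test_vanishes_with_horizon(self, example_chain):
        assert gate_constant(example_chain, 2, 1e-12) == pytest.approx(0.0, abs=1e-11)
        with pytest.raises(ValueError):
            gate_constant(example_chain, 2, 0.0)

    def test_gate_position_validated(self, example_chain):
        with pytest.raises(ValueError):
            gate_constant(example_chain, 1, 1.0)
        with pytest.raises(ValueError):
            gate_constant(example_chain, 6, 1.0)


class TestUngatedChain:
    def test_is_valid_truncated_chain(self, example_chain):
        un = ungated_chain(example_chain, 3, 10.0)
        assert un.path.states == example_chain.path.states[2:]
        assert un.alphas == example_chain.alphas[2:]
        assert 0 < un.C <= example_chain.C

    def test_cascade_masses_match_recursion(self, example_chain):
        """The recurrent initial masses equal the closed-form cascade
        levels evaluated at the horizon."""
        dt = 10.0
        chains = cascade_chains(example_chain, dt)
        bound = cascade_upper_bound(example_chain, np.array([dt]))
        for level, chain in enumerate(chains):
            assert chain.C == pytest.approx(bound.values[0, level], abs=1e-12)


class TestCascadeBound:
    def test_first_level_is_initial_mass(self, example_chain):
        times = np.linspace(0.0, 10.0, 11)
        bound = cascade_upper_bound(example_chain, times)
        np.testing.assert_allclose(bound.values[:, 0], 1.0)

    def test_levels_nonnegative_and_nondecreasing(self, example_chain):
        times = np.linspace(0.0, 10.0, 200)
        bound = cascade_upper_bound(example_chain, times)
        assert (bound.values >= -1e-15).all()
        assert (np.diff(bound.values, axis=0) >= -1e-12).all()

    def test_saturates_when_nothing_leaks(self):
        """If every transition captures the full exit rate (beta = alpha),
        each cascade factor tends to one."""
        chain = PathChain(
            path=Path(((0,), (1,), (2,)), (0, 0)), C=1.0,
            alphas=(1.0, 2.0, 0.5), betas=(1.0, 2.0),
        )
        bound = cascade_upper_bound(chain, np.array([200.0]))
        assert bound.terminal[0] == pytest.approx(1.0, abs=1e-12)

    def test_absorbing_interior_state_rejected(self):
        chain = PathChain(
            path=Path(((0,), (1,), (2,)), (0, 0)), C=1.0,
            alphas=(1.0, 0.0, 0.5), betas=(1.0, 0.0),
        )
        with pytest.raises(ValueError, match="absorbing"):
            cascade_upper_bound(chain, np.array([1.0]))


class TestDominance:
    @pytest.mark.parametrize(
        "fixture", ["bd_x0_2", "bd_case1", "bd_case2", "bd_case3"]
    )
    def test_worked_chain_bound_holds(self, fixture):
        """The cascade bound dominates the exact path probability on the
        worked birth-death chain across all studied parameter cases."""
        system, x0 = rp.make_fixture(fixture)
        path = Path(((0, 0), (1, 0), (1, 1), (1, 2), (1, 3)), (0, 1, 1, 1))
        chain = PathChain.from_path(system, x0, path)
        report = verify_bound(chain, np.linspace(0.01, 10.0, 500))
        assert report.passed(tol=1e-12)
        assert report.pointwise_margin_min >= -1e-12
        assert (report.integral_margins >= -1e-12).all()

    def test_single_gate_integral_dominance(self, example_chain):
        """Un-gating at the second state dominates the original chain in
        time-integral at that state, over every sub-interval of the
        horizon."""
        dt = 10.0
        polys, _ = path_chain_solve(example_chain, times=None)
        un = ungated_chain(example_chain, 2, dt)
        un_polys, _ = path_chain_solve(un, times=None)
        for t in (0.5, 2.0, 5.0, dt):
            assert polys[1].integrate(t) <= un_polys[0].integrate(t) + 1e-12

    def test_single_gate_pointwise_dominance_is_transient(self, example_chain):
        """Down-chain pointwise dominance of a single un-gated chain holds
        early but genuinely fails at late times: the original chain keeps
        being fed from upstream while the un-gated one only decays.  Both
        sides are cross-checked against the ODE oracle so the crossover is
        a property of the construction, not of the closed form."""
        dt = 10.0
        times = np.array([0.5, 1.0, 3.0, 10.0])
        _, values = path_chain_solve(example_chain, times)
        un = ungated_chain(example_chain, 2, dt)
        _, un_values = path_chain_solve(un, times)
        np.testing.assert_allclose(
            un_values, path_chain_solve_ode(un, times), atol=1e-10
        )
        # dominated while the un-gated head start wins ...
        assert (values[:2, 2:] <= un_values[:2, 1:] + 1e-12).all()
        # ... but not once the original chain's resupply takes over
        assert (values[2:, 2] > un_values[2:, 1]).all()

    @pytest.mark.parametrize("seed", range(20))
    def test_integral_dominance_on_random_chains(self, seed):
        rng = np.random.default_rng(1000 + seed)
        chain = random_chain(rng, m=int(rng.integers(4, 8)))
        report = verify_bound(chain, np.linspace(0.05, 5.0, 50), dt=5.0)
        assert (report.integral_margins >= -1e-12).all()

    def test_two_state_chain_bound(self):
        """For a two-state path the cascade bound is the single-gate
        factor, which dominates the divided-difference solution."""
        chain = PathChain(
            path=Path(((0,), (1,)), (0,)), C=1.0, alphas=(1.0, 1.1), betas=(1.0,)
        )
        report = verify_bound(chain, np.linspace(0.01, 10.0, 200))
        assert report.pointwise_margin_min >= -1e-12
        assert len(report.integral_margins) == 0
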