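"""Exponential polynomials, path enumeration, and the chain decomposition."""

import numpy as np
import pytest
from scipy.integrate import quad

import rxnpaths as rp
from rxnpaths.paths import (
    ExpPolynomial,
    Path,
    PathCapError,
    PathChain,
    chain_sink,
    path_chain_solve,
    path_chain_solve_ode,
)

from conftest import random_chain


class TestExpPolynomial:
    @pytest.mark.parametrize("seed", range(5))
    def test_convolution_matches_quadrature(self, seed):
        """Oracle: numerical quadrature of int_0^t e^{-a(t-s)} f(s) ds."""
        rng = np.random.default_rng(seed)
        terms = [
            (rng.uniform(-2, 2), int(rng.integers(0, 3)), rng.uniform(0, 3))
            for _ in range(3)
        ]
        f = ExpPolynomial(terms)
        a = rng.uniform(0, 3)
        g = f.convolve_exp(a)
        for t in (0.3, 1.0, 4.0):
            ref, _ = quad(lambda s: np.exp(-a * (t - s)) * f(s), 0, t,
                          epsabs=1e-13, epsrel=1e-12)
            assert g(t) == pytest.approx(ref, abs=1e-10)

    def test_convolution_with_equal_rate_gives_power(self):
        f = ExpPolynomial.exponential(1.0, 2.0)
        g = f.convolve_exp(2.0)
        assert g.terms == [(1.0, 1, 2.0)]

    @pytest.mark.parametrize("seed", range(3))
    def test_running_integral_matches_quadrature(self, seed):
        rng = np.random.default_rng(100 + seed)
        f = ExpPolynomial([
            (rng.uniform(-1, 1), int(rng.integers(0, 3)), rng.uniform(0, 2))
            for _ in range(3)
        ] + [(0.5, 1, 0.0)])
        for T in (0.5, 2.0):
            ref, _ = quad(f, 0, T, epsabs=1e-13)
            assert f.integrate(T) == pytest.approx(ref, abs=1e-11)

    def test_product_evaluates_pointwise(self):
        f = ExpPolynomial([(2.0, 1, 0.5)])
        g = ExpPolynomial([(3.0, 0, 1.0), (1.0, 2, 0.0)])
        t = np.array([0.0, 0.7, 3.0])
        np.testing.assert_allclose((f * g)(t), f(t) * g(t), atol=1e-14)

    def test_nearby_rates_are_merged(self):
        f = ExpPolynomial([(1.0, 0, 1.0), (2.0, 0, 1.0 + 1e-14)])
        assert len(f.terms) == 1
        assert f.terms[0][0] == pytest.approx(3.0)


class TestPathEnumeration:
    def test_two_orders_when_both_feasible(self, bd2):
        system, x0 = bd2
        paths = rp.enumerate_paths(system, x0, (1, 1))
        assert [p.reaction_sequence for p in paths] == [(0, 1), (1, 0)]

    def test_blocked_transition_pruned(self, bd0):
        """From an empty start the death-first order has zero propensity."""
        system, x0 = bd0
        paths = rp.enumerate_paths(system, x0, (1, 1))
        assert [p.reaction_sequence for p in paths] == [(0, 1)]

    def test_origin_has_single_trivial_path(self, bd0):
        system, x0 = bd0
        paths = rp.enumerate_paths(system, x0, (0, 0))
        assert len(paths) == 1 and len(paths[0]) == 1

    def test_lattice_path_count(self, bd2):
        """With x0 high enough that nothing blocks, the count is the
        binomial number of interleavings."""
        system, x0 = rp.birth_death(x0=10, cb=1.0, cd=0.1)
        paths = rp.enumerate_paths(system, x0, (3, 2))
        assert len(paths) == 10  # C(5, 2)

    def test_cap_overflow(self, bd2):
        system, x0 = rp.birth_death(x0=10)
        with pytest.raises(PathCapError):
            rp.enumerate_paths(system, x0, (4, 4), cap=10)


class TestPathChainSolve:
    def test_two_state_closed_form(self):
        chain = PathChain(
            path=Path(((0,), (1,)), (0,)), C=1.0, alphas=(1.0, 1.1), betas=(1.0,)
        )
        polys, _ = path_chain_solve(chain)
        expected = (np.exp(-1.0) - np.exp(-1.1)) / 0.1
        assert polys[1](1.0) == pytest.approx(expected, abs=1e-14)
        assert expected == pytest.approx(0.3501, abs=1e-4)

    def test_first_state_at_time_zero(self, example_chain):
        polys, values = path_chain_solve(example_chain, np.array([0.0]))
        assert values[0, 0] == pytest.approx(1.0)
        assert np.max(np.abs(values[0, 1:])) <= 1e-12

    def test_equal_rate_degenerate_limit(self):
        """When both exit rates coincide the solution is C*beta*t*e^{-at}."""
        chain = PathChain(
            path=Path(((0,), (1,)), (0,)), C=0.8, alphas=(1.5, 1.5), betas=(0.6,)
        )
        polys, _ = path_chain_solve(chain)
        for t in (0.5, 2.0):
            assert polys[1](t) == pytest.approx(0.8 * 0.6 * t * np.exp(-1.5 * t),
                                                abs=1e-14)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_ode_oracle(self, seed):
        """Closed form vs direct integration of the (m+1)-state generator
        (off-chain flow absorbed into the sink)."""
        rng = np.random.default_rng(seed)
        chain = random_chain(rng, m=int(rng.integers(3, 7)))
        times = np.linspace(0.0, 8.0, 9)
        _, values = path_chain_solve(chain, times)
        ode = path_chain_solve_ode(chain, times)
        np.testing.assert_allclose(values, ode, atol=1e-10)

    def test_repeated_rates_along_chain(self, bd2):
        """A chain revisiting a population repeats exit rates; the solver
        must handle the induced t^k terms without cancellation."""
        system, x0 = bd2
        path = Path(((0, 0), (1, 0), (1, 1), (2, 1), (2, 2)), (0, 1, 0, 1))
        chain = PathChain.from_path(system, x0, path)
        assert len(set(chain.alphas)) < len(chain.alphas)
        times = np.linspace(0.0, 6.0, 7)
        _, values = path_chain_solve(chain, times)
        np.testing.assert_allclose(values, path_chain_solve_ode(chain, times),
                                   atol=1e-10)

    def test_conservation_with_sink(self, example_chain):
        polys, values = path_chain_solve(example_chain, np.linspace(0, 10, 11))
        sink = chain_sink(example_chain, polys)
        total = values.sum(axis=1) + sink(np.linspace(0, 10, 11))
        np.testing.assert_allclose(total, example_chain.C, atol=1e-10)

    def test_long_chain_falls_back_to_ode(self):
        rng = np.random.default_rng(0)
        chain = random_chain(rng, m=60)
        times = np.array([1.0])
        polys, values = path_chain_solve(chain, times)
        assert polys is None
        assert values.shape == (1, 60)


class TestDecomposition:
    def test_reachable_states_decompose_exactly(self, bd2):
        system, x0 = bd2
        report = rp.decompose_state(system, x0, (1, 1), np.array([0.5, 1.0, 5.0]))
        assert report.n_paths == 2
        assert report.max_abs_diff <= 1e-8

    def test_single_firing_state_is_one_path(self, bd2):
        system, x0 = bd2
        report = rp.decompose_state(system, x0, (0, 1), np.array([1.0, 5.0]))
        assert report.n_paths == 1
        assert report.max_abs_diff <= 1e-10

    def test_origin_decomposes_to_exit_exponential(self, bd2):
        system, x0 = bd2
        times = np.array([0.5, 2.0])
        report = rp.decompose_state(system, x0, (0, 0), times)
        expected = np.exp(-1.2 * times)
        np.testing.assert_allclose(report.path_sum, expected, atol=1e-12)
        np.testing.assert_allclose(report.cme_prob, expected, atol=1e-10)

    def test_each_path_bounded_by_state_probability(self, bd2):
        system, x0 = bd2
        report = rp.decompose_state(system, x0, (2, 2), np.array([1.0, 5.0]))
        assert (report.per_path >= -1e-14).all()
        assert (report.per_path <= report.cme_prob[:, None] + 1e-10).all()
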