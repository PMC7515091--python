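"""End-to-end consistency battery over the built-in fixtures.

Each check exercises one of the framework's exact identities or bounds —
generator triangularity, probability conservation, the shell outflow/tail
identity, the path-chain decomposition, cascade dominance, and agreement
between the analytical solver and Monte-Carlo simulation — and reports a
margin so near-misses are visible, not just pass/fail.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import cme, gating, paths, ssa
from .fixtures import make_fixture
from .statespace import build_generator, expand_shells, verify_triangular

__all__ = ["CheckResult", "validate_all"]


@dataclass(frozen=True)
class CheckResult:
    name: str
    passed: bool
    margin: float
    detail: str


def _example_chain(system, x0):
    """The worked 5-state birth–death chain (0,0)->(1,0)->(1,1)->(1,2)->(1,3)."""
    path = paths.Path(
        states=((0, 0), (1, 0), (1, 1), (1, 2), (1, 3)),
        reaction_sequence=(0, 1, 1, 1),
    )
    return paths.PathChain.from_path(system, x0, path, C=1.0)


def validate_all(eps: float = 1e-8, seed: int = 42, n_ssa: int = 20_000,
                 fixtures=("bd_x0_0", "bd_x0_2", "pure_birth",
                           "dimerization_toy", "toggle_toy")) -> list:
    """Run the full property battery; returns a list of :class:`CheckResult`."""
    results = []
    # battery horizon: long enough that every fixture is far from its
    # initial condition, short enough that the default shell cap certifies
    # the 3-reaction toys at eps
    times = np.linspace(0.5, 8.0, 16)

    # -- generator structure on every fixture
    worst = np.inf
    ok = True
    for name in fixtures:
        system, x0 = make_fixture(name)
        gen = build_generator(expand_shells(system, x0, 8), system, x0)
        tri, violations = verify_triangular(gen)
        ok &= tri
        diag = gen.diagonal
        eigs = np.sort(np.linalg.eigvals(gen.A_star.toarray()).real)
        worst = min(worst, -float(np.max(np.abs(eigs - np.sort(diag)))))
    results.append(CheckResult(
        "generator triangular + spectrum on diagonal", ok and worst > -1e-8,
        worst, "max |eig - diag| over fixtures",
    ))

    # -- conservation and monotone tails
    worst = np.inf
    for name in fixtures:
        system, x0 = make_fixture(name)
        dist = cme.solve_reaction_cme(system, x0, times, eps=eps)
        defect = np.max(np.abs(dist.probs.sum(axis=1) + dist.tail - 1.0))
        worst = min(worst, 1e-10 - float(defect))
        masses = dist.shell_masses(len(times) - 1)
        tails = np.array(
            [masses[m:].sum() + dist.tail[-1] for m in range(len(masses))]
        )
        worst = min(worst, -float(np.max(np.diff(tails))))
    results.append(CheckResult(
        "conservation + monotone shell tails", worst >= -1e-10, worst,
        "min margin over fixtures",
    ))

    # -- shell outflow identity
    system, x0 = make_fixture("bd_x0_0")
    dist = cme.solve_reaction_cme(system, x0, np.array([5.0]), eps=eps)
    worst = np.inf
    for m in (1, 2, 3):
        phi, psi = cme.tail_mass_identity(system, x0, dist, m)
        worst = min(worst, 1e-6 - abs(phi - psi))
    results.append(CheckResult(
        "shell outflow equals tail mass", worst >= 0, worst,
        "1e-6 minus |phi_m - psi_{m+1}|, m in 1..3",
    ))

    # -- push-forward vs direct species solve
    grid = np.array([1.0, 5.0, 10.0])
    rdist = cme.solve_reaction_cme(system, x0, grid, eps=eps)
    spec_pf = cme.push_forward(rdist, system, x0)
    spec_direct = cme.solve_species_fsp(system, x0, grid, eps=eps)
    diff = max(
        abs(spec_pf.prob_of(x, i) - spec_direct.prob_of(x, i))
        for i in range(len(grid))
        for x in set(spec_pf.states) | set(spec_direct.states)
    )
    results.append(CheckResult(
        "push-forward matches species FSP", diff <= 2 * eps, 2 * eps - diff,
        "max abs difference over states and times",
    ))

    # -- path-chain decomposition
    system, x0 = make_fixture("bd_x0_2")
    space = expand_shells(system, x0, 4)
    worst = np.inf
    for shell in space.shells:
        for r in shell.states:
            rep = paths.decompose_state(system, x0, r, np.array([0.5, 1.0, 5.0]))
            worst = min(worst, 1e-8 - rep.max_abs_diff)
    results.append(CheckResult(
        "path-chain decomposition", worst >= 0, worst,
        "1e-8 minus max decomposition defect, all |r| <= 4",
    ))

    # -- cascade dominance on the worked chain
    chain = _example_chain(system, x0)
    report = gating.verify_bound(chain, np.linspace(0.001, 10.0, 500))
    margin = min(
        report.pointwise_margin_min,
        float(report.integral_margins.min()) if len(report.integral_margins) else np.inf,
    )
    results.append(CheckResult(
        "cascade bound dominates path probability", report.passed(), margin,
        "min pointwise/integral margin",
    ))

    # -- SSA vs solver
    system, x0 = make_fixture("bd_x0_0")
    emp = ssa.ensemble_distribution(system, x0, 10.0, n_ssa, seed)
    sdist = cme.solve_species_fsp(system, x0, np.array([10.0]), eps=1e-10)
    ref = {x: sdist.prob_of(x, 0) for x in sdist.states}
    freqs = {
        x: c / emp.n_trajectories for x, c in emp.species_counts.items()
    }
    tv = ssa.total_variation(freqs, ref)
    # expected TV of a multinomial sample scales like sqrt(k / n)
    tol = 3.0 * np.sqrt(len(ref) / n_ssa)
    results.append(CheckResult(
        "SSA ensemble matches solved distribution", tv <= tol, tol - tv,
        f"TV distance {tv:.4f} vs tolerance {tol:.4f} at n={n_ssa}",
    ))

    return results
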