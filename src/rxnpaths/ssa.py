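"""Seeded Gillespie simulation over reaction counts.

The direct-method stochastic simulation algorithm draws an exponential
waiting time at the total propensity and picks the firing reaction with
probability proportional to its propensity.  Tracking the cumulative
tally of fired reactions realises the random-time-change (Kurtz)
representation directly; the species trajectory is recovered from the
tally and the initial population through the bridge map.

Reproducibility: every trajectory gets its own generator keyed by
``(master seed, trajectory index)`` through NumPy's ``SeedSequence``
spawning (``default_rng([seed, index])``), so ensembles are bitwise
reproducible regardless of execution order or parallelism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ReactionSystem, _check_species_state

__all__ = ["Trajectory", "EmpiricalDistribution", "simulate",
           "ensemble_distribution", "total_variation"]


@dataclass(frozen=True)
class Trajectory:
    """One realisation: jump times, fired reactions, terminal states.

    ``reaction_indices`` are 0-based (the package's internal convention;
    reports print them 1-based).  The terminal reaction-count state is
    the cumulative tally of the indices.
    """

    jump_times: np.ndarray
    reaction_indices: np.ndarray
    r_final: tuple
    x_final: tuple
    seed: object

    @property
    def num_jumps(self) -> int:
        return len(self.jump_times)


@dataclass(frozen=True)
class EmpiricalDistribution:
    """Monte-Carlo frequencies over reaction-count and species states."""

    reaction_counts: dict
    species_counts: dict
    n_trajectories: int
    t: float

    def reaction_freq(self, r) -> float:
        return self.reaction_counts.get(tuple(r), 0) / self.n_trajectories

    def species_freq(self, x) -> float:
        return self.species_counts.get(tuple(x), 0) / self.n_trajectories

    def species_stderr(self, x) -> float:
        """Binomial standard error of the species frequency."""
        p = self.species_freq(x)
        return float(np.sqrt(p * (1 - p) / self.n_trajectories))


def _prepare(system: ReactionSystem):
    """Unpack the network into plain-python structures for the hot loop."""
    nr = system.num_reactions
    rates = [float(c) for c in system.rate_constants]
    reactants = [
        [(i, int(s)) for i, s in enumerate(system.reactant_stoich[n]) if s]
        for n in range(nr)
    ]
    net = [[int(v) for v in system.net_stoich[n]] for n in range(nr)]
    hooks = [
        system.propensity_hooks.get(system.reaction_names[n]) for n in range(nr)
    ]
    return nr, rates, reactants, net, hooks


def _propensities(x, nr, rates, reactants, hooks):
    a = []
    for n in range(nr):
        if hooks[n] is not None:
            a.append(float(hooks[n](tuple(x))))
            continue
        v = rates[n]
        for i, s in reactants[n]:
            xi = x[i]
            if xi < s:
                v = 0.0
                break
            if s == 1:
                v *= xi
            elif s == 2:
                v *= xi * (xi - 1) / 2.0
            else:
                from math import comb

                v *= comb(xi, s)
        a.append(v)
    return a


def simulate(system: ReactionSystem, x0, t_end: float, seed) -> Trajectory:
    """One exact SSA trajectory on ``[0, t_end]``, fully determined by
    ``seed`` (an int or a sequence acceptable to ``default_rng``).

    Query-time convention is right-continuous: a jump at exactly
    ``t_end`` is included.  Absorbing states end the trajectory early.
    """
    x0 = _check_species_state(system, x0, "x0")
    if t_end < 0:
        raise ValueError("t_end must be >= 0")
    rng = np.random.default_rng(seed)
    nr, rates, reactants, net, hooks = _prepare(system)
    x = list(x0)
    r = [0] * nr
    t = 0.0
    jump_times, fired = [], []
    while True:
        a = _propensities(x, nr, rates, reactants, hooks)
        a0 = sum(a)
        if a0 <= 0.0:
            break
        t += rng.exponential(1.0 / a0)
        if t > t_end:
            break
        u = rng.random() * a0
        acc = 0.0
        n = nr - 1
        for j in range(nr):
            acc += a[j]
            if u < acc:
                n = j
                break
        r[n] += 1
        for i, dv in enumerate(net[n]):
            if dv:
                x[i] += dv
        jump_times.append(t)
        fired.append(n)
    return Trajectory(
        jump_times=np.asarray(jump_times),
        reaction_indices=np.asarray(fired, dtype=np.int64),
        r_final=tuple(r),
        x_final=tuple(x),
        seed=seed,
    )


def ensemble_distribution(system: ReactionSystem, x0, t: float, n: int,
                          seed: int) -> EmpiricalDistribution:
    """Empirical state distributions at time ``t`` from ``n`` independent
    trajectories, each keyed by ``(seed, trajectory index)``."""
    if n < 1:
        raise ValueError("need at least one trajectory")
    rxn: dict = {}
    spc: dict = {}
    for i in range(n):
        traj = simulate(system, x0, t, seed=[seed, i])
        rxn[traj.r_final] = rxn.get(traj.r_final, 0) + 1
        spc[traj.x_final] = spc.get(traj.x_final, 0) + 1
    return EmpiricalDistribution(
        reaction_counts=rxn, species_counts=spc, n_trajectories=n, t=t
    )


def total_variation(freqs: dict, reference: dict) -> float:
    """Total-variation distance between two distributions given as
    ``state -> probability`` mappings."""
    states = set(freqs) | set(reference)
    return 0.5 * sum(
        abs(freqs.get(s, 0.0) - reference.get(s, 0.0)) for s in states
    )
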