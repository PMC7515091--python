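"""Shell-partitioned reaction-count state space and its triangular generator.

Because reactions only ever fire (never un-fire), the reaction-count state
space partitions into disjoint *shells*: shell ``m`` holds exactly the
states reachable in ``m`` firings from the origin, i.e. those with total
count ``|r|_1 = m``.  Ordering the states shell by shell makes the
generator of the reaction-counts master equation strictly lower
triangular off the diagonal — probability only flows from lower to higher
shells — so its spectrum is read off the diagonal, which is the negated
total exit propensity of each state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .model import (
    ReactionSystem,
    _check_species_state,
    reaction_propensity_vector,
)

__all__ = ["Shell", "OrderedStateSpace", "Generator", "expand_shells",
           "build_generator", "verify_triangular"]


@dataclass(frozen=True)
class Shell:
    """States reachable in exactly ``m`` firings (all with ``|r|_1 = m``)."""

    m: int
    states: tuple

    def __len__(self) -> int:
        return len(self.states)


@dataclass(frozen=True)
class OrderedStateSpace:
    """Breadth-first enumeration of reachable reaction-count states.

    States are ordered block-by-shell and lexicographically within a
    shell; ``index`` maps each state tuple to its row in that ordering.
    """

    shells: tuple
    index: dict = field(compare=False)
    M: int

    @property
    def states(self) -> list:
        return [s for shell in self.shells for s in shell.states]

    @property
    def num_states(self) -> int:
        return sum(len(s) for s in self.shells)

    def shell_sizes(self) -> list:
        return [len(s) for s in self.shells]

    def shell_of(self, row: int) -> int:
        """Shell depth of the state stored at a given row."""
        acc = 0
        for shell in self.shells:
            acc += len(shell)
            if row < acc:
                return shell.m
        raise IndexError(row)

    def shell_slice(self, m: int) -> slice:
        start = sum(len(s) for s in self.shells[:m])
        return slice(start, start + len(self.shells[m]))


@dataclass(frozen=True)
class Generator:
    """Sparse generator ``A*`` of the reaction-counts master equation.

    Diagonal entries are ``-alpha(x0, r)`` (total exit rate, including
    transitions that would leave the truncation — outflow is never
    redirected); the off-diagonal entry at (row ``r + 1_n``, column ``r``)
    is ``alpha_n(x0, r)``.
    """

    A_star: sp.csc_matrix
    space: OrderedStateSpace

    @property
    def diagonal(self) -> np.ndarray:
        return self.A_star.diagonal()


def expand_shells(system: ReactionSystem, x0, M: int) -> OrderedStateSpace:
    """Enumerate the reachable state space up to shell depth ``M``.

    Breadth-first from the origin; a successor ``r + 1_n`` is added only
    through an edge of positive propensity.  States whose implied
    population would be negative carry zero propensity and are therefore
    never stored.  Empty shells occur when the process is absorbed.
    """
    x0 = _check_species_state(system, x0, "x0")
    if M < 0:
        raise ValueError("M must be >= 0")
    nr = system.num_reactions
    origin = (0,) * nr
    shells = [Shell(0, (origin,))]
    frontier = [origin]
    for m in range(1, M + 1):
        nxt = set()
        for r in frontier:
            alpha = reaction_propensity_vector(system, x0, r)
            for n in range(nr):
                if alpha[n] > 0.0:
                    nxt.add(r[:n] + (r[n] + 1,) + r[n + 1:])
        frontier = sorted(nxt)
        shells.append(Shell(m, tuple(frontier)))
    index = {}
    for shell in shells:
        for s in shell.states:
            index[s] = len(index)
    return OrderedStateSpace(shells=tuple(shells), index=index, M=M)


def build_generator(space: OrderedStateSpace, system: ReactionSystem, x0) -> Generator:
    """Assemble ``A*`` over the shell-ordered states.

    Transitions leaving shell ``M`` appear only in the diagonal (as
    outflow), so retained column sums are ``<= 0`` and the lost mass is
    exactly the truncation tail.
    """
    if space.num_states == 0:
        raise ValueError("state space is empty")
    rows, cols, vals = [], [], []
    nr = system.num_reactions
    for r, col in space.index.items():
        alpha = reaction_propensity_vector(system, x0, r)
        rows.append(col)
        cols.append(col)
        vals.append(-float(alpha.sum()))
        for n in range(nr):
            if alpha[n] > 0.0:
                succ = r[:n] + (r[n] + 1,) + r[n + 1:]
                row = space.index.get(succ)
                if row is not None:
                    rows.append(row)
                    cols.append(col)
                    vals.append(float(alpha[n]))
    A = sp.csc_matrix(
        (vals, (rows, cols)), shape=(space.num_states, space.num_states)
    )
    return Generator(A_star=A, space=space)


def verify_triangular(gen: Generator):
    """Check that every off-diagonal entry lies strictly below the diagonal.

    Returns ``(ok, violations)`` where violations is a list of offending
    ``(row, col, value)`` triples (empty when the shell-block ordering
    makes the matrix lower triangular, as the forward-stepping structure
    guarantees).
    """
    coo = gen.A_star.tocoo()
    violations = [
        (int(i), int(j), float(v))
        for i, j, v in zip(coo.row, coo.col, coo.data)
        if i < j and v != 0.0
    ]
    return len(violations) == 0, violations
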