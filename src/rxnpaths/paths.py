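"""Path chains: exact probabilities of single trajectories through the
reaction-count lattice.

An *admissible path* is a sequence of reaction-count states in which each
step increments exactly one reaction tally.  Restricting the Markov chain
to such a path — with every off-path transition absorbed into a sink —
gives a *path chain* whose state probabilities have an exact closed form:
each is a finite sum of ``c * t^k * exp(-lambda t)`` terms, built by
convolving the previous state's probability against the exit exponential
of the current state.  Summing the terminal probability over every
admissible path from the origin to a state ``r`` recovers the full
reaction-counts CME probability of ``r`` — the path-chain decomposition.

The convolutions are carried out symbolically in the exponential-
polynomial representation.  Repeated exit rates along a path (guaranteed
to occur whenever a population is revisited) are merged into ``t^k``
terms rather than evaluated as divided differences, which avoids the
catastrophic cancellation of the nearly-equal-rate closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .model import (
    ReactionSystem,
    _check_species_state,
    reaction_propensity_vector,
)

__all__ = [
    "ExpPolynomial",
    "Path",
    "PathChain",
    "PathCapError",
    "enumerate_paths",
    "path_chain_solve",
    "path_chain_solve_ode",
    "decompose_state",
    "DecompositionReport",
]

#: Two rates within this relative tolerance are treated as equal, producing
#: a t^k term instead of a divided difference.
RATE_MERGE_RTOL = 1e-12


class PathCapError(RuntimeError):
    """Path enumeration exceeded its combinatorial cap."""


def _rates_equal(a: float, b: float) -> bool:
    return abs(a - b) <= RATE_MERGE_RTOL * max(abs(a), abs(b), 1.0)


class ExpPolynomial:
    """A finite sum ``sum_i c_i * t^{k_i} * exp(-lambda_i t)``.

    Closed under addition, scaling, multiplication, and the convolution
    ``int_0^t exp(-a (t-s)) f(s) ds`` — the operations needed to solve a
    path chain exactly.  Terms with equal ``(k, lambda)`` are merged;
    rates are compared with :data:`RATE_MERGE_RTOL` relative tolerance.
    """

    __slots__ = ("terms",)

    def __init__(self, terms=()):
        merged: list = []
        for c, k, lam in terms:
            if c == 0.0:
                continue
            if k < 0 or lam < 0:
                raise ValueError("powers and rates must be non-negative")
            for i, (c2, k2, lam2) in enumerate(merged):
                if k2 == k and _rates_equal(lam2, lam):
                    merged[i] = (c2 + c, k2, lam2)
                    break
            else:
                merged.append((float(c), int(k), float(lam)))
        self.terms = [t for t in merged if t[0] != 0.0]

    @classmethod
    def exponential(cls, coeff: float, rate: float) -> "ExpPolynomial":
        """The single term ``coeff * exp(-rate t)``."""
        return cls([(coeff, 0, rate)])

    @classmethod
    def constant(cls, value: float) -> "ExpPolynomial":
        return cls([(value, 0, 0.0)])

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        out = np.zeros_like(t)
        for c, k, lam in self.terms:
            out = out + c * t**k * np.exp(-lam * t)
        return out if out.ndim else float(out)

    def __add__(self, other: "ExpPolynomial") -> "ExpPolynomial":
        return ExpPolynomial(self.terms + other.terms)

    def __sub__(self, other: "ExpPolynomial") -> "ExpPolynomial":
        return self + other.scale(-1.0)

    def scale(self, factor: float) -> "ExpPolynomial":
        return ExpPolynomial([(c * factor, k, lam) for c, k, lam in self.terms])

    def __mul__(self, other: "ExpPolynomial") -> "ExpPolynomial":
        terms = [
            (c1 * c2, k1 + k2, l1 + l2)
            for c1, k1, l1 in self.terms
            for c2, k2, l2 in other.terms
        ]
        return ExpPolynomial(terms)

    def convolve_exp(self, a: float) -> "ExpPolynomial":
        """Return ``g(t) = int_0^t exp(-a (t-s)) f(s) ds`` in closed form."""
        out = []
        for c, k, lam in self.terms:
            if _rates_equal(a, lam):
                # int_0^t e^{-a(t-s)} s^k e^{-a s} ds = t^{k+1}/(k+1) e^{-a t}
                out.append((c / (k + 1), k + 1, a))
                continue
            mu = a - lam
            sign = 1.0
            for j in range(k + 1):
                coeff = c * sign * math.factorial(k) / math.factorial(k - j) / mu ** (j + 1)
                out.append((coeff, k - j, lam))
                sign = -sign
            out.append((-c * (-1.0) ** k * math.factorial(k) / mu ** (k + 1), 0, a))
        return ExpPolynomial(out)

    def integral_poly(self) -> "ExpPolynomial":
        """The running integral ``F(t) = int_0^t f(s) ds`` (with F(0)=0)."""
        out = []
        for c, k, lam in self.terms:
            if lam == 0.0:
                out.append((c / (k + 1), k + 1, 0.0))
                continue
            # int_0^t s^k e^{-lam s} ds
            out.append((c * math.factorial(k) / lam ** (k + 1), 0, 0.0))
            for j in range(k + 1):
                out.append(
                    (-c * math.factorial(k) / math.factorial(k - j) / lam ** (j + 1),
                     k - j, lam)
                )
        return ExpPolynomial(out)

    def integrate(self, T: float) -> float:
        """Definite integral over ``[0, T]``."""
        return float(self.integral_poly()(T))

    def __repr__(self) -> str:
        if not self.terms:
            return "ExpPolynomial(0)"
        parts = [f"{c:g}*t^{k}*e^(-{lam:g}t)" for c, k, lam in self.terms]
        return "ExpPolynomial(" + " + ".join(parts) + ")"


@dataclass(frozen=True)
class Path:
    """An admissible path: consecutive states differ by one unit firing."""

    states: tuple
    reaction_sequence: tuple

    def __post_init__(self):
        if len(self.states) != len(self.reaction_sequence) + 1:
            raise ValueError("a path of m states has m-1 transitions")

    def __len__(self) -> int:
        return len(self.states)


@dataclass(frozen=True)
class PathChain:
    """A CTMC restricted to one admissible path, plus a sink.

    ``alphas[k]`` is the full exit rate out of the k-th path state (all
    reactions, including those that leave the path — that flow is
    absorbed by the sink); ``betas[k]`` is the along-chain rate from
    state k to k+1, i.e. the propensity of the transition's reaction
    evaluated at state k.  ``C`` is the initial mass placed on the first
    state; the sink holds the complement so total mass stays ``C``.
    """

    path: Path
    C: float
    alphas: tuple
    betas: tuple

    def __post_init__(self):
        if not 0 < self.C <= 1:
            raise ValueError("C must lie in (0, 1]")
        m = len(self.path)
        if len(self.alphas) != m or len(self.betas) != m - 1:
            raise ValueError("need one exit rate per state, one along-chain rate per step")
        for b, a in zip(self.betas, self.alphas):
            if b < 0 or b > a + 1e-12:
                raise ValueError("along-chain rate must satisfy 0 <= beta <= alpha")

    @classmethod
    def from_path(cls, system: ReactionSystem, x0, path: Path, C: float = 1.0) -> "PathChain":
        """Attach rates inherited from the reaction network."""
        x0 = _check_species_state(system, x0, "x0")
        alphas, betas = [], []
        for i, g in enumerate(path.states):
            vec = reaction_propensity_vector(system, x0, g)
            alphas.append(float(vec.sum()))
            if i < len(path.states) - 1:
                betas.append(float(vec[path.reaction_sequence[i]]))
        return cls(path=path, C=C, alphas=tuple(alphas), betas=tuple(betas))

    def truncated(self, j: int, C_new: float) -> "PathChain":
        """The chain over the tail path ``(g_j, ..., g_m)`` (1-based ``j``)
        with a fresh initial mass — the building block of un-gating."""
        if not 1 <= j <= len(self.path):
            raise ValueError(f"j must lie in 1..{len(self.path)}")
        i = j - 1
        return PathChain(
            path=Path(self.path.states[i:], self.path.reaction_sequence[i:]),
            C=C_new,
            alphas=self.alphas[i:],
            betas=self.betas[i:],
        )


def enumerate_paths(system: ReactionSystem, x0, r, cap: int = 100_000) -> list:
    """All admissible paths from the origin to ``r`` with positive
    propensity at every step.

    The number of such paths grows multinomially in the entries of ``r``;
    enumeration raises :class:`PathCapError` past ``cap``.  Paths are
    returned in lexicographic order of their reaction sequences.
    Zero-propensity transitions are pruned: the chains they would carry
    are identically zero.
    """
    x0 = _check_species_state(system, x0, "x0")
    r = tuple(int(v) for v in r)
    nr = system.num_reactions
    origin = (0,) * nr
    out: list = []

    def dfs(state: tuple, seq: list):
        if state == r:
            states = [origin]
            for n in seq:
                prev = states[-1]
                states.append(prev[:n] + (prev[n] + 1,) + prev[n + 1:])
            out.append(Path(states=tuple(states), reaction_sequence=tuple(seq)))
            if len(out) > cap:
                raise PathCapError(
                    f"more than {cap} admissible paths lead to {r}"
                )
            return
        alpha = reaction_propensity_vector(system, x0, state)
        for n in range(nr):
            if state[n] < r[n] and alpha[n] > 0.0:
                dfs(state[:n] + (state[n] + 1,) + state[n + 1:], seq + [n])

    dfs(origin, [])
    return out


def path_chain_solve(chain: PathChain, times=None):
    """Exact per-state probabilities of a path chain.

    The first state decays as ``C exp(-alpha_1 t)``; each subsequent
    state is the previous one convolved against its own exit
    exponential, scaled by the along-chain rate.  Returns the list of
    :class:`ExpPolynomial` solutions (one per path state) and, when a
    time grid is given, the evaluated ``(T, m)`` probability array.

    Chains longer than 50 states fall back to a stiff ODE solve on the
    chain generator, where the symbolic term count would be unwieldy.
    """
    if len(chain.path) > 50:
        if times is None:
            raise ValueError("chains longer than 50 states need an explicit time grid")
        return None, path_chain_solve_ode(chain, times)
    polys = [ExpPolynomial.exponential(chain.C, chain.alphas[0])]
    for k in range(1, len(chain.path)):
        prev = polys[k - 1]
        polys.append(prev.convolve_exp(chain.alphas[k]).scale(chain.betas[k - 1]))
    if times is None:
        return polys, None
    times = np.asarray(times, dtype=float)
    values = np.column_stack([p(times) for p in polys])
    return polys, values


def chain_generator(chain: PathChain) -> np.ndarray:
    """Dense ``(m+1) x (m+1)`` generator of the chain including its sink.

    Along-chain flow at rate beta, everything else into the sink (last
    row), diagonal the negated full exit rate.
    """
    m = len(chain.path)
    A = np.zeros((m + 1, m + 1))
    for k in range(m):
        A[k, k] = -chain.alphas[k]
        if k < m - 1:
            A[k + 1, k] = chain.betas[k]
            A[m, k] = chain.alphas[k] - chain.betas[k]
        else:
            A[m, k] = chain.alphas[k]
    return A


def path_chain_solve_ode(chain: PathChain, times) -> np.ndarray:
    """Numerical oracle: integrate the chain's (m+1)-state generator."""
    times = np.asarray(times, dtype=float)
    A = chain_generator(chain)
    u0 = np.zeros(len(chain.path) + 1)
    u0[0] = chain.C
    t_span = (0.0, float(times[-1]) if times[-1] > 0 else 1e-9)
    sol = solve_ivp(
        lambda t, u: A @ u, t_span, u0, t_eval=np.clip(times, *t_span),
        method="LSODA", rtol=1e-12, atol=1e-14,
    )
    return sol.y.T[:, : len(chain.path)]


def chain_sink(chain: PathChain, polys) -> ExpPolynomial:
    """Sink mass as the conservation complement ``C - sum(states)``."""
    total = ExpPolynomial.constant(chain.C)
    for p in polys:
        total = total - p
    return total


@dataclass(frozen=True)
class DecompositionReport:
    """Comparison of the CME probability of ``r`` with its path-chain sum."""

    r: tuple
    times: np.ndarray
    cme_prob: np.ndarray
    path_sum: np.ndarray
    n_paths: int
    per_path: np.ndarray = field(repr=False)

    @property
    def max_abs_diff(self) -> float:
        return float(np.max(np.abs(self.cme_prob - self.path_sum)))


def decompose_state(system: ReactionSystem, x0, r, times, eps: float = 1e-12,
                    cap: int = 100_000) -> DecompositionReport:
    """Verify that ``p(R(t) = r)`` equals the sum of its path chains.

    Both sides are computed independently: the left from the truncated
    CME solve, the right by enumerating every admissible path into ``r``
    and evaluating each chain's terminal probability in closed form
    (each sub-chain keeps initial mass 1; no renormalisation).
    """
    from .cme import solve_reaction_cme  # local import to avoid a cycle

    r = tuple(int(v) for v in r)
    times = np.asarray(times, dtype=float)
    depth = int(sum(r))
    paths = enumerate_paths(system, x0, r, cap=cap)
    per_path = np.zeros((len(times), len(paths)))
    for j, path in enumerate(paths):
        chain = PathChain.from_path(system, x0, path, C=1.0)
        _, values = path_chain_solve(chain, times)
        per_path[:, j] = values[:, -1]
    path_sum = per_path.sum(axis=1)

    dist = solve_reaction_cme(
        system, x0, times, eps=eps, start_depth=max(8, depth + 1)
    )
    cme_prob = dist.prob_of(r)
    return DecompositionReport(
        r=r, times=times, cme_prob=cme_prob, path_sum=path_sum,
        n_paths=len(paths), per_path=per_path,
    )
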