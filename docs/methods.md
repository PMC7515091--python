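# Methods

This note records the mathematical conventions, numerical choices, and
known limitations behind `rxnpaths`.

## Model and kinetics

A network of `Ns` species and `Nr` reactions is specified by reactant and
product stoichiometry matrices and positive rate constants.  Propensities
follow stochastic mass action in binomial form,
`a_n(x) = c_n · Π_i C(x_i, s_{n,i})`, which reduces to `c_b` for a
zeroth-order birth and `c_d·x` for first-order decay, and counts distinct
reactant combinations for higher orders.  Bimolecular constants are taken
as already volume-scaled (units 1/time throughout).  Non-mass-action
kinetics can be attached in code as per-reaction hooks keyed by reaction
name; model files themselves stay mass-action only, so a file fully
determines a model.

States are dense integer tuples.  Species and reactions are 0-indexed in
the API and 1-indexed in command-line reports.

## Reaction-count state space and truncation

The reaction-count space is enumerated breadth-first from the origin in
shells of constant total firing count, lexicographically ordered within a
shell so outputs are byte-reproducible.  A successor is stored only when
reached through a transition of positive propensity; tallies whose implied
population would be negative have zero propensity by construction and are
never stored.  (One could instead keep such states with zero rates — the
probabilities are identical; exclusion just keeps the matrices smaller.)

Under the shell-block ordering the generator is strictly lower triangular
off the diagonal; this is asserted (`verify_triangular`), not assumed.
Transitions that would leave the deepest retained shell contribute only to
the diagonal, so retained column sums are ≤ 0 and the missing mass is
exactly the truncation tail.

The truncation loop starts at depth 8 and doubles until the tail at the
final output time is below `eps` (default `1e-8`), with hard caps at depth
64 and 2×10⁶ states.  Because probability only flows forward, the tail is
largest at the final time; one depth therefore serves the whole grid (this
monotonicity is asserted on every solve).  A finite state space that is
fully enumerated (an empty frontier shell) terminates the loop regardless
of `eps`.

## Solving the linear dynamics

The nested convolution integrals of the analytical solution are not
evaluated by nested quadrature — error would accumulate multiplicatively
down the shells.  The solver instead propagates the initial point mass
with the action of the sparse matrix exponential (`expm_multiply`,
Al-Mohy–Higham), stepping from one output time to the next; this is
mathematically identical to the recursion and accurate to machine
precision on these well-conditioned triangular systems.  The same scheme
drives the direct species-space finite-state-projection solve used as the
independent cross-check of the push-forward identity.

The shell outflow/tail identity is evaluated with adaptive quadrature
(`scipy.integrate.quad`, relative tolerance `1e-9`) on the
matrix-exponential solution, so the two sides of the identity come from
genuinely different computations.

The initial mass `C` defaults to 1 (the full CME).  Values below 1 are
supported so sub-chains can be restarted with accumulated mass without
renormalisation; the solution is linear in `C`.

## Path chains and the exponential-polynomial engine

A path chain restricts the CTMC to one admissible firing sequence, with
all off-path flow absorbed in a sink.  Its state probabilities are
computed symbolically as sums of `c·t^k·e^{−λt}` terms: the first state is
`C·e^{−α₁t}`, and each later state is the previous one convolved against
its own exit exponential and scaled by the along-chain rate.  The
representation is closed under this convolution, under products (used for
the cascade bound), and under running integrals (used for gate constants).

Equal exit rates along a path are guaranteed to occur — any revisited
population repeats its rate — and the divided-difference closed form is
then catastrophically ill-conditioned.  Rates within `1e-12` relative
tolerance are therefore merged into `t^k` terms, which is exact in the
degenerate limit (`C·β·t·e^{−αt}` for a two-state chain with equal rates).
Chains longer than 50 states fall back to a stiff ODE solve
(`LSODA`, rtol `1e-12`, atol `1e-14`) on the `(m+1)`-state chain
generator; the same ODE route is kept available at every length as an
independent oracle.

Path enumeration is depth-first in lexicographic reaction order, prunes
zero-propensity transitions (their chains are identically zero), and
raises past a configurable cap (default 10⁵) since the number of
interleavings grows multinomially.

## Gating, un-gating, and the cascade bound

Gating at position `j` accumulates
`C_j = β(g_{j−1},g_j) ∫₀^{Δt} p(chain at g_{j−1}) ds`, evaluated exactly
from the antiderivative; un-gating restarts the truncated chain
`(g_j,…,g_m)` from that mass.  Cascading gates across every transition
gives the recursion `u_n(t) = (β_{n−1}/α_{n−1})(1−e^{−α_{n−1}t})
u_{n−1}(t)` with `u_1 = C`, built symbolically as exponential-polynomial
products; `u_n(t)` equals the recurrent initial mass of the level-`n`
un-gated chain with horizon `t`.

Two distinct dominance statements are checked by `verify_bound`, and the
report labels them separately:

* **Time-integral dominance** at each interior state: the integral of the
  level-`(k−1)` un-gated chain at `g_k` over `[0, Δt]` dominates that of
  the original chain.  This holds in every test, including 20 randomized
  chains.
* **Pointwise dominance of the terminal cascade level** `u_m(t)` over the
  exact path probability.  This holds at all grid points in every studied
  case and is what the bound is used for in practice — but it is treated
  as an empirical observation: `verify_bound` measures margins and flags
  violations rather than assuming the inequality.

One caution for users of single gates: pointwise dominance of a *single*
un-gated chain at downstream states is transient.  It holds while the
un-gated chain's head start dominates but genuinely reverses at later
times, because the original chain keeps being resupplied from upstream
while the un-gated chain only decays (the test suite pins the crossover on
the worked birth–death chain against an ODE oracle).  Only the
time-integral form of single-gate dominance is robust; rely on the
cascade's `u_m` for pointwise statements and check the reported margin.

Whether the gap `u_m(t) − p(path)` converges to zero as `t → ∞` is left
open; the tools report the gap and make no claim.

## Stochastic simulation

The simulator is the direct method: exponential waiting time at the total
propensity, reaction chosen proportionally to its propensity, cumulative
tally giving the reaction-count state and, through the bridge map, the
species state.  Every trajectory uses `numpy`'s `default_rng([seed, i])`
(SeedSequence spawning keyed by master seed and trajectory index), so
ensembles are bitwise reproducible and order-independent.  Snapshots are
right-continuous: a jump at exactly the query time is included.

Monte-Carlo comparisons use total-variation distance with a
`3·sqrt(k/n)` tolerance (`k` support size, `n` trajectories) — the
expected multinomial sampling error at three sigma.

## Test problems

The bundled fixtures are deliberately small.  The birth–death family
(`c_b = 1.0–2.0`, `c_d = 0.1–0.2`, `x0 ∈ {0, 2}`) is the canonical
boundary-dominated case: near-zero populations make the death channel
switch on and off, which is exactly the regime where population-level
approximations fail and the reaction-count formulation is informative.
The dimerization and annihilation toys add multi-species stoichiometry
and second-order kinetics so that shell enumeration, the binomial
propensity form, and the push-forward are exercised beyond one species.
These fixtures probe the *exact identities* of the framework — which hold
at machine precision regardless of scale — but say nothing about
performance on large networks (see limitations).

Default problem sizes in the test and acceptance runs (grids to `t = 10`,
`eps = 1e-8`, tallies up to five firings, 10⁵ trajectories) were chosen so
the full battery completes in well under a minute on one core while
leaving each check orders of magnitude of headroom against its tolerance.

## Limitations

* State enumeration is explicit; the reaction-count space grows quickly
  with the number of reactions and with time horizon.  The intended scale
  is networks of a handful of reactions over moderate horizons.
* Stationary behaviour is out of scope: the reaction-count process never
  stops moving forward, so only transient (finite-time) questions are
  posed.
* Rate constants are time-independent; time-varying propensities are not
  supported.
* Path enumeration is exhaustive up to the cap; there is no importance
  sampling or automatic selection of dominant paths.
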