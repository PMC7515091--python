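"""Built-in toy reaction networks.

The birth–death fixtures reproduce the worked parameterisations used
throughout the package's validation suite; the remaining fixtures add
multi-species stoichiometry (a dimerisation cycle and a two-species
annihilation toggle) so that structural properties are exercised beyond
a single species.
"""

from __future__ import annotations

import numpy as np

from .model import ReactionSystem

__all__ = ["FIXTURE_NAMES", "make_fixture", "birth_death"]


def birth_death(x0: int = 0, cb: float = 1.0, cd: float = 0.1):
    """Birth–death process: ``0 -> X`` at rate ``cb``, ``X -> 0`` at
    rate ``cd * x``.  Returns ``(system, x0)``."""
    system = ReactionSystem(
        species_names=("X",),
        reaction_names=("birth", "death"),
        reactant_stoich=np.array([[0], [1]]),
        product_stoich=np.array([[1], [0]]),
        rate_constants=np.array([cb, cd]),
    )
    return system, (int(x0),)


def _pure_birth():
    system = ReactionSystem(
        species_names=("X",),
        reaction_names=("birth",),
        reactant_stoich=np.array([[0]]),
        product_stoich=np.array([[1]]),
        rate_constants=np.array([1.0]),
    )
    return system, (0,)


def _dimerization_toy():
    # 0 -> A, A + A -> B, B -> 0
    system = ReactionSystem(
        species_names=("A", "B"),
        reaction_names=("production", "dimerization", "degradation"),
        reactant_stoich=np.array([[0, 0], [2, 0], [0, 1]]),
        product_stoich=np.array([[1, 0], [0, 1], [0, 0]]),
        rate_constants=np.array([1.0, 0.5, 0.2]),
    )
    return system, (0, 0)


def _toggle_toy():
    # 0 -> A, 0 -> B, A + B -> 0
    system = ReactionSystem(
        species_names=("A", "B"),
        reaction_names=("make_A", "make_B", "annihilate"),
        reactant_stoich=np.array([[0, 0], [0, 0], [1, 1]]),
        product_stoich=np.array([[1, 0], [0, 1], [0, 0]]),
        rate_constants=np.array([1.0, 0.8, 0.5]),
    )
    return system, (1, 1)


_FIXTURES = {
    "bd_x0_0": lambda: birth_death(0, 1.0, 0.1),
    "bd_x0_2": lambda: birth_death(2, 1.0, 0.1),
    "bd_case1": lambda: birth_death(2, 1.0, 0.15),
    "bd_case2": lambda: birth_death(2, 1.0, 0.2),
    "bd_case3": lambda: birth_death(2, 2.0, 0.15),
    "pure_birth": _pure_birth,
    "dimerization_toy": _dimerization_toy,
    "toggle_toy": _toggle_toy,
}

FIXTURE_NAMES = tuple(_FIXTURES)


def make_fixture(name: str):
    """Return ``(ReactionSystem, x0)`` for a named fixture."""
    try:
        factory = _FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture '{name}'; available: {', '.join(FIXTURE_NAMES)}"
        ) from None
    return factory()
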