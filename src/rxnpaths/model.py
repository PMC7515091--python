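"""Reaction networks, state conventions, and propensity evaluation.

A stochastic reaction network with ``Ns`` species and ``Nr`` reactions is
described by its reactant/product stoichiometry and mass-action rate
constants.  Two discrete state spaces are used throughout the package:

* **species counts** ``x`` — a vector of ``Ns`` non-negative populations
  (the state space Omega of the classical chemical master equation);
* **reaction counts** ``r`` — a vector of ``Nr`` non-negative integers
  counting how many times each reaction has fired since time zero (the
  state space Lambda of the reaction-counts master equation).

The two are bridged by the affine map ``Gamma(x0, r) = x0 + S^T r`` where
``S`` is the net stoichiometry: knowing the initial population and the
reaction tallies determines the current population.  States are plain
tuples of Python ints so they can key dictionaries; reactions and species
are 0-indexed internally and 1-indexed in user-facing reports.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "ReactionSystem",
    "ModelError",
    "gamma_map",
    "gamma_pullback",
    "species_propensity",
    "propensity_vector",
    "reaction_propensity",
    "reaction_propensity_vector",
    "total_propensity",
    "load_model",
    "save_model",
    "system_from_dict",
    "system_to_dict",
]

#: A species-count state: tuple of Ns non-negative ints.
SpeciesState = tuple
#: A reaction-count state: tuple of Nr non-negative ints.
ReactionCountState = tuple


class ModelError(ValueError):
    """Raised on malformed models, states, or model files."""


@dataclass(frozen=True)
class ReactionSystem:
    """A mass-action reaction network.

    Parameters
    ----------
    species_names : sequence of str
        Labels for the ``Ns`` species.
    reaction_names : sequence of str
        Labels for the ``Nr`` reactions.
    reactant_stoich : (Nr, Ns) int array
        Copies of each species consumed by each reaction.
    product_stoich : (Nr, Ns) int array
        Copies of each species produced by each reaction.
    rate_constants : (Nr,) float array
        Stochastic mass-action constants ``c_n`` in 1/time units;
        bimolecular constants are taken as already volume-scaled.
    propensity_hooks : dict, optional
        ``reaction name -> f(x)`` overrides for non-mass-action kinetics.
        Model files remain mass-action only; hooks are attached in code.
    """

    species_names: tuple
    reaction_names: tuple
    reactant_stoich: np.ndarray
    product_stoich: np.ndarray
    rate_constants: np.ndarray
    propensity_hooks: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        react = np.asarray(self.reactant_stoich, dtype=np.int64)
        prod = np.asarray(self.product_stoich, dtype=np.int64)
        rates = np.asarray(self.rate_constants, dtype=float)
        object.__setattr__(self, "species_names", tuple(self.species_names))
        object.__setattr__(self, "reaction_names", tuple(self.reaction_names))
        object.__setattr__(self, "reactant_stoich", react)
        object.__setattr__(self, "product_stoich", prod)
        object.__setattr__(self, "rate_constants", rates)
        ns, nr = len(self.species_names), len(self.reaction_names)
        if ns < 1 or nr < 1:
            raise ModelError("a system needs at least one species and one reaction")
        if react.shape != (nr, ns) or prod.shape != (nr, ns):
            raise ModelError(
                f"stoichiometry must be shaped ({nr}, {ns}); got "
                f"reactants {react.shape}, products {prod.shape}"
            )
        if (react < 0).any() or (prod < 0).any():
            raise ModelError("stoichiometric coefficients must be non-negative")
        if rates.shape != (nr,):
            raise ModelError(f"expected {nr} rate constants, got {rates.shape}")
        if not (rates > 0).all():
            raise ModelError("all rate constants must be positive")

    @property
    def num_species(self) -> int:
        return len(self.species_names)

    @property
    def num_reactions(self) -> int:
        return len(self.reaction_names)

    @property
    def net_stoich(self) -> np.ndarray:
        """Net population change per reaction: products minus reactants."""
        return self.product_stoich - self.reactant_stoich


def _check_species_state(system: ReactionSystem, x, name: str = "x") -> tuple:
    x = tuple(int(v) for v in x)
    if len(x) != system.num_species:
        raise ModelError(
            f"{name} has {len(x)} entries; system has {system.num_species} species"
        )
    if any(v < 0 for v in x):
        raise ModelError(f"{name} has a negative population: {x}")
    return x


def _check_count_state(system: ReactionSystem, r) -> tuple:
    r = tuple(int(v) for v in r)
    if len(r) != system.num_reactions:
        raise ModelError(
            f"r has {len(r)} entries; system has {system.num_reactions} reactions"
        )
    if any(v < 0 for v in r):
        raise ModelError(f"reaction counts must be non-negative: {r}")
    return r


def gamma_map(system: ReactionSystem, x0, r):
    """Map reaction counts to the implied population state.

    Returns ``x0 + sum_n nu_n r_n`` as a tuple when every entry is
    non-negative, and ``None`` (the explicit "outside Omega" marker) when
    the tallies would imply a negative population.  A negative-population
    state is never returned.
    """
    x0 = _check_species_state(system, x0, "x0")
    r = _check_count_state(system, r)
    x = np.asarray(x0, dtype=np.int64) + np.asarray(r, dtype=np.int64) @ system.net_stoich
    if (x < 0).any():
        return None
    return tuple(int(v) for v in x)


def gamma_pullback(system: ReactionSystem, x0, x, max_total: int) -> list:
    """All reaction-count states with at most ``max_total`` total firings
    whose image under :func:`gamma_map` equals ``x``.

    The result is deterministic: lexicographically sorted tuples.  The map
    is generally many-to-one (different firing tallies can produce the same
    population), so the returned set may have more than one element.
    """
    x0 = _check_species_state(system, x0, "x0")
    x = _check_species_state(system, x)
    if max_total < 0:
        raise ModelError("max_total must be >= 0")
    nr = system.num_reactions
    net = system.net_stoich
    target = np.asarray(x, dtype=np.int64) - np.asarray(x0, dtype=np.int64)
    out = []

    def recurse(idx: int, budget: int, prefix: list, partial: np.ndarray):
        if idx == nr - 1:
            # last coordinate: try every remaining count
            for k in range(budget + 1):
                if ((partial + k * net[idx]) == target).all():
                    out.append(tuple(prefix + [k]))
            return
        for k in range(budget + 1):
            recurse(idx + 1, budget - k, prefix + [k], partial + k * net[idx])

    recurse(0, max_total, [], np.zeros(system.num_species, dtype=np.int64))
    return sorted(out)


def species_propensity(system: ReactionSystem, x, n: int) -> float:
    """Propensity ``a_n(x)`` of reaction ``n`` (0-indexed) in population ``x``.

    Stochastic mass action: ``c_n * prod_i C(x_i, s_{n,i})`` with ``s`` the
    reactant stoichiometry and ``C`` the binomial coefficient; zero whenever
    any population falls short of its reactant requirement.  A registered
    hook for the reaction name takes precedence.
    """
    x = _check_species_state(system, x)
    if not 0 <= n < system.num_reactions:
        raise ModelError(f"reaction index {n} out of range 0..{system.num_reactions - 1}")
    hook = system.propensity_hooks.get(system.reaction_names[n])
    if hook is not None:
        return float(hook(x))
    a = float(system.rate_constants[n])
    for xi, si in zip(x, system.reactant_stoich[n]):
        if si:
            if xi < si:
                return 0.0
            a *= math.comb(xi, int(si))
    return a


def propensity_vector(system: ReactionSystem, x) -> np.ndarray:
    """All ``Nr`` species-state propensities at ``x``."""
    return np.array(
        [species_propensity(system, x, n) for n in range(system.num_reactions)]
    )


def reaction_propensity(system: ReactionSystem, x0, r, n: int) -> float:
    """Propensity of reaction ``n`` in reaction-count state ``r``.

    Inherited from the species setting through the bridge map: equal to
    ``a_n(Gamma(x0, r))`` when the implied population is valid, else 0.
    """
    x = gamma_map(system, x0, r)
    if x is None:
        return 0.0
    return species_propensity(system, x, n)


def reaction_propensity_vector(system: ReactionSystem, x0, r) -> np.ndarray:
    """All ``Nr`` reaction-count propensities ``alpha_n(x0, r)``."""
    x = gamma_map(system, x0, r)
    if x is None:
        return np.zeros(system.num_reactions)
    return propensity_vector(system, x)


def total_propensity(system: ReactionSystem, x0, r) -> float:
    """Total exit rate ``alpha(x0, r) = sum_n alpha_n(x0, r)``."""
    return float(reaction_propensity_vector(system, x0, r).sum())


# ---------------------------------------------------------------------------
# model file I/O


def _schema_error(path: str, msg: str) -> ModelError:
    return ModelError(f"model file, at {path}: {msg}")


def system_from_dict(data: dict):
    """Build ``(ReactionSystem, x0)`` from a parsed model dictionary.

    Expected layout::

        {"species": ["X"], "x0": [0],
         "reactions": [{"name": "birth", "reactants": {}, "products": {"X": 1},
                        "rate": 1.0}, ...]}
    """
    if not isinstance(data, dict):
        raise _schema_error("$", f"expected a mapping, got {type(data).__name__}")
    for key in ("species", "x0", "reactions"):
        if key not in data:
            raise _schema_error("$", f"missing required key '{key}'")
    unknown = set(data) - {"species", "x0", "reactions"}
    if unknown:
        raise _schema_error("$", f"unknown keys {sorted(unknown)}")

    species = data["species"]
    if not isinstance(species, list) or not all(isinstance(s, str) for s in species):
        raise _schema_error("$.species", "expected a list of species names")
    if len(set(species)) != len(species):
        raise _schema_error("$.species", "duplicate species names")
    sp_index = {s: i for i, s in enumerate(species)}

    x0 = data["x0"]
    if (
        not isinstance(x0, list)
        or len(x0) != len(species)
        or not all(isinstance(v, int) and v >= 0 for v in x0)
    ):
        raise _schema_error(
            "$.x0", f"expected {len(species)} non-negative integers"
        )

    reactions = data["reactions"]
    if not isinstance(reactions, list) or not reactions:
        raise _schema_error("$.reactions", "expected a non-empty list")
    names, react, prod, rates = [], [], [], []
    for i, rx in enumerate(reactions):
        loc = f"$.reactions[{i}]"
        if not isinstance(rx, dict):
            raise _schema_error(loc, "expected a mapping")
        for key in ("name", "reactants", "products", "rate"):
            if key not in rx:
                raise _schema_error(loc, f"missing required key '{key}'")
        if not isinstance(rx["name"], str):
            raise _schema_error(f"{loc}.name", "expected a string")
        row_r = [0] * len(species)
        row_p = [0] * len(species)
        for field_name, row in (("reactants", row_r), ("products", row_p)):
            entry = rx[field_name]
            if not isinstance(entry, dict):
                raise _schema_error(f"{loc}.{field_name}", "expected a mapping")
            for sp, count in entry.items():
                if sp not in sp_index:
                    raise _schema_error(
                        f"{loc}.{field_name}", f"unknown species '{sp}'"
                    )
                if not isinstance(count, int) or count < 1:
                    raise _schema_error(
                        f"{loc}.{field_name}.{sp}",
                        "stoichiometric coefficient must be a positive integer",
                    )
                row[sp_index[sp]] = count
        rate = rx["rate"]
        if not isinstance(rate, (int, float)) or not rate > 0:
            raise _schema_error(f"{loc}.rate", "expected a positive number")
        names.append(rx["name"])
        react.append(row_r)
        prod.append(row_p)
        rates.append(float(rate))
    if len(set(names)) != len(names):
        raise _schema_error("$.reactions", "duplicate reaction names")

    system = ReactionSystem(
        species_names=species,
        reaction_names=names,
        reactant_stoich=np.array(react, dtype=np.int64),
        product_stoich=np.array(prod, dtype=np.int64),
        rate_constants=np.array(rates),
    )
    return system, tuple(x0)


def system_to_dict(system: ReactionSystem, x0) -> dict:
    """Inverse of :func:`system_from_dict` (round-trips up to key order)."""
    x0 = _check_species_state(system, x0, "x0")
    reactions = []
    for n, name in enumerate(system.reaction_names):
        reactants = {
            system.species_names[i]: int(c)
            for i, c in enumerate(system.reactant_stoich[n])
            if c
        }
        products = {
            system.species_names[i]: int(c)
            for i, c in enumerate(system.product_stoich[n])
            if c
        }
        reactions.append(
            {
                "name": name,
                "reactants": reactants,
                "products": products,
                "rate": float(system.rate_constants[n]),
            }
        )
    return {
        "species": list(system.species_names),
        "x0": list(x0),
        "reactions": reactions,
    }


def load_model(path):
    """Load ``(ReactionSystem, x0)`` from a JSON or YAML model file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        try:
            data = json.loads(text)
        except json.JSONDecodeError as e:
            raise ModelError(f"{path}: invalid JSON at line {e.lineno}: {e.msg}") from e
    else:
        try:
            data = yaml.safe_load(text)
        except yaml.YAMLError as e:
            raise ModelError(f"{path}: invalid YAML: {e}") from e
    try:
        return system_from_dict(data)
    except ModelError as e:
        raise ModelError(f"{path}: {e}") from e


def save_model(system: ReactionSystem, x0, path) -> None:
    """Write a model file; format chosen by extension (.json else YAML)."""
    path = Path(path)
    data = system_to_dict(system, x0)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
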