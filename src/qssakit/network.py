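"""Reaction networks with elementary and non-elementary rate laws.

A :class:`ReactionNetwork` is the single source of truth for both the
deterministic derivatives (macroscopic rate laws ``f_j``) and the stochastic
propensities (``a_j = Omega * f_j(n/Omega)``).  Rate laws are either
``mass_action`` (rate constant times reactant concentrations with
multiplicity) or ``closed_form`` (a whitelisted-grammar expression over
species and parameters -- Hill, Michaelis-Menten, QSS roots).

Conservation laws support the elimination of dependent species: a species
declared with role ``eliminated`` is replaced inside all rate laws by
``total - sum(coeff * retained)`` via :func:`apply_conservation`.

Networks may carry a positive, state-dependent *prefactor* per species
(needed for prefactor-type QSS reductions): the ODE engine divides the
assembled derivative of that species by it.  SSA engines reject prefactored
networks; :meth:`ReactionNetwork.without_prefactor` yields the stochastic
counterpart whose propensities are the unprefactored reaction rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .expressions import Expr, parse_expression

__all__ = [
    "SpeciesSpec",
    "RateLaw",
    "Reaction",
    "ReactionNetwork",
    "ModelPair",
    "apply_conservation",
    "DefinitionError",
    "RateLawError",
    "StateError",
]


class DefinitionError(ValueError):
    """Inconsistent network definition (unknown species, bad constants...)."""


class RateLawError(ValueError):
    """A rate law evaluated to a negative or non-finite value."""


class StateError(ValueError):
    """A state violates nonnegativity or a conservation law."""


@dataclass(frozen=True)
class SpeciesSpec:
    """A chemical species.

    ``role`` is one of ``slow``, ``fast`` or ``eliminated``; ``physical``
    range ``[lo, hi]`` bounds admissible values (``hi`` may be ``inf`` for
    unbounded species such as an mRNA pool).
    """

    name: str
    role: str = "slow"
    initial: float = 0.0
    lo: float = 0.0
    hi: float = math.inf

    def __post_init__(self):
        if self.role not in ("slow", "fast", "eliminated"):
            raise DefinitionError(f"bad role {self.role!r} for species {self.name}")
        if not (self.lo <= self.initial <= self.hi):
            raise DefinitionError(
                f"initial value {self.initial} of {self.name} outside "
                f"physical range [{self.lo}, {self.hi}]"
            )


@dataclass(frozen=True)
class RateLaw:
    """Macroscopic rate law: mass-action or closed-form expression."""

    kind: str  # "mass_action" | "closed_form"
    rate_constant: float | None = None
    expression: str | Expr | None = None
    parameters: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind == "mass_action":
            if self.rate_constant is None or self.rate_constant <= 0:
                raise DefinitionError("mass_action law needs a positive rate constant")
        elif self.kind == "closed_form":
            if self.expression is None:
                raise DefinitionError("closed_form law needs an expression")
            for name, value in self.parameters.items():
                if not value > 0:
                    raise DefinitionError(f"parameter {name} must be positive, got {value}")
        else:
            raise DefinitionError(f"unknown rate-law kind {self.kind!r}")


@dataclass(frozen=True)
class Reaction:
    """A reaction channel: stoichiometries plus one rate law."""

    name: str
    reactants: dict = field(default_factory=dict)
    products: dict = field(default_factory=dict)
    rate_law: RateLaw | None = None

    def net_change(self, species: str) -> int:
        return self.products.get(species, 0) - self.reactants.get(species, 0)


def _mass_action_expr(reaction: Reaction, microscopic: bool, volume: float) -> Expr:
    k = reaction.rate_law.rate_constant
    parts = [repr(float(k))]
    for sp, m in sorted(reaction.reactants.items()):
        if microscopic and m > 1:
            # combinatorial n(n-1).../Omega^(m-1) form, in concentration units
            for i in range(m):
                parts.append(f"({sp} - {i / volume})" if i else sp)
            parts.append(repr(1.0 / math.factorial(m)))
        else:
            parts.extend([sp] * m)
    return parse_expression("*".join(parts))


class ReactionNetwork:
    """Species, reactions, conservation laws and a system volume."""

    def __init__(
        self,
        species: list[SpeciesSpec],
        reactions: list[Reaction],
        conservation_laws: list[tuple[dict, float]] | None = None,
        volume: float = 1.0,
        prefactors: dict | None = None,
        microscopic_exact: bool = False,
        name: str = "network",
    ):
        if volume <= 0:
            raise DefinitionError("volume must be positive")
        self.species = list(species)
        self.reactions = list(reactions)
        self.conservation_laws = [(dict(c), float(t)) for c, t in (conservation_laws or [])]
        self.volume = float(volume)
        self.prefactors = {k: parse_expression(v) for k, v in (prefactors or {}).items()}
        self.microscopic_exact = microscopic_exact
        self.name = name
        self._validate()
        self._compiled = None
        self._rhs_parts = None

    # -- structure ---------------------------------------------------------

    @property
    def species_order(self) -> list[str]:
        return [s.name for s in self.species]

    @property
    def species_index(self) -> dict:
        return {s.name: i for i, s in enumerate(self.species)}

    @property
    def has_prefactor(self) -> bool:
        return bool(self.prefactors)

    def spec(self, name: str) -> SpeciesSpec:
        for s in self.species:
            if s.name == name:
                return s
        raise DefinitionError(f"unknown species {name!r}")

    def _validate(self) -> None:
        declared = set(self.species_order)
        if len(declared) != len(self.species):
            raise DefinitionError("duplicate species names")
        for rxn in self.reactions:
            if rxn.rate_law is None:
                raise DefinitionError(f"reaction {rxn.name} has no rate law")
            for sp in list(rxn.reactants) + list(rxn.products):
                if sp not in declared:
                    raise DefinitionError(f"reaction {rxn.name} names unknown species {sp!r}")
            unknown = self.rate_expression(rxn).names - declared
            if unknown:
                raise DefinitionError(
                    f"rate law of {rxn.name} names unknown species {sorted(unknown)}"
                )
        for sp in self.prefactors:
            if sp not in declared:
                raise DefinitionError(f"prefactor on unknown species {sp!r}")
        elim_counts = {s.name: 0 for s in self.species if s.role == "eliminated"}
        for coeffs, total in self.conservation_laws:
            for sp, c in coeffs.items():
                if sp not in declared:
                    raise DefinitionError(f"conservation law names unknown species {sp!r}")
                if sp in elim_counts:
                    elim_counts[sp] += 1
            value = sum(c * self.spec(sp).initial for sp, c in coeffs.items())
            if not math.isclose(value, total, rel_tol=1e-9, abs_tol=1e-12):
                raise DefinitionError(
                    f"initial state violates conservation law {coeffs} = {total} (got {value})"
                )
            # conserved combinations must be untouched by every reaction
            for rxn in self.reactions:
                net = sum(c * rxn.net_change(sp) for sp, c in coeffs.items())
                if net != 0:
                    raise DefinitionError(
                        f"reaction {rxn.name} changes conserved combination {coeffs}"
                    )
        for sp, n in elim_counts.items():
            if n != 1:
                raise DefinitionError(
                    f"eliminated species {sp} must appear in exactly one conservation law"
                )

    # -- rate laws ---------------------------------------------------------

    def rate_expression(self, reaction: Reaction) -> Expr:
        """The macroscopic rate f_j as an expression in species names only."""
        law = reaction.rate_law
        if law.kind == "mass_action":
            return _mass_action_expr(reaction, self.microscopic_exact, self.volume)
        expr = parse_expression(law.expression)
        if law.parameters:
            expr = expr.substitute({k: float(v) for k, v in law.parameters.items()})
        return expr

    def _parts(self):
        if self._rhs_parts is None:
            order = self.species_order
            funcs = [self.rate_expression(r).compile(order) for r in self.reactions]
            stoich = np.zeros((len(self.reactions), len(order)))
            for j, rxn in enumerate(self.reactions):
                for i, sp in enumerate(order):
                    stoich[j, i] = rxn.net_change(sp)
            pref = {
                self.species_index[sp]: expr.compile(order)
                for sp, expr in self.prefactors.items()
            }
            self._rhs_parts = (funcs, stoich, pref)
        return self._rhs_parts

    def _as_vector(self, state) -> np.ndarray:
        if isinstance(state, dict):
            unknown = set(state) - set(self.species_order)
            if unknown:
                raise DefinitionError(f"unknown species in state: {sorted(unknown)}")
            return np.array([state.get(s, self.spec(s).initial) for s in self.species_order])
        return np.asarray(state, dtype=float)

    def rates(self, state) -> np.ndarray:
        """Macroscopic reaction rates f_j at a concentration state."""
        x = self._as_vector(state)
        funcs, _, _ = self._parts()
        out = np.array([f(x) for f in funcs], dtype=float)
        if np.any(out < -1e-9) or not np.all(np.isfinite(out)):
            bad = self.reactions[int(np.argmin(out))].name
            raise RateLawError(f"rate law of {bad} evaluated to a negative/non-finite value")
        return np.maximum(out, 0.0)

    def evaluate_rhs(self, state) -> dict:
        """Deterministic time derivative of every species (prefactor applied)."""
        x = self._as_vector(state)
        funcs, stoich, pref = self._parts()
        dx = self.rates(x) @ stoich
        for i, pf in pref.items():
            p = pf(x)
            if not p > 0:
                raise RateLawError(f"prefactor of {self.species_order[i]} not positive")
            dx[i] /= p
        return dict(zip(self.species_order, dx))

    def rhs_function(self):
        """Vectorized ``f(x) -> dx`` over the species order (for integrators)."""
        funcs, stoich, pref = self._parts()

        def rhs(x: np.ndarray) -> np.ndarray:
            rates = np.array([f(x) for f in funcs], dtype=float)
            dx = rates @ stoich
            for i, pf in pref.items():
                dx[i] /= pf(x)
            return dx

        return rhs

    def propensities(self, counts) -> np.ndarray:
        """Stochastic propensities a_j = Omega * f_j(n/Omega)."""
        n = self._as_vector(counts)
        if np.any(n < 0):
            raise StateError("negative count")
        return self.volume * self.rates(n / self.volume)

    def initial_state(self) -> dict:
        return {s.name: s.initial for s in self.species}

    def initial_counts(self) -> dict:
        out = {}
        for s in self.species:
            n = s.initial * self.volume
            if abs(n - round(n)) > 1e-6:
                raise StateError(
                    f"initial count of {s.name} is not an integer at volume {self.volume}"
                )
            out[s.name] = int(round(n))
        return out

    # -- derived networks ---------------------------------------------------

    def without_prefactor(self) -> "ReactionNetwork":
        """Same reactions, prefactors dropped (the stochastic counterpart)."""
        if not self.prefactors:
            return self
        return ReactionNetwork(
            self.species,
            self.reactions,
            self.conservation_laws,
            self.volume,
            prefactors=None,
            microscopic_exact=self.microscopic_exact,
            name=self.name,
        )

    def with_volume(self, volume: float) -> "ReactionNetwork":
        return ReactionNetwork(
            self.species,
            self.reactions,
            self.conservation_laws,
            volume,
            prefactors={k: v for k, v in self.prefactors.items()},
            microscopic_exact=self.microscopic_exact,
            name=self.name,
        )

    def compiled(self):
        """Bytecode program for the numba SSA kernel (cached)."""
        if self._compiled is None:
            from ._ssa_kernel import compile_network

            self._compiled = compile_network(self)
        return self._compiled

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "volume": self.volume,
            "species": [
                {
                    "name": s.name,
                    "role": s.role,
                    "initial": s.initial,
                    "range": [s.lo, None if math.isinf(s.hi) else s.hi],
                }
                for s in self.species
            ],
            "reactions": [
                {
                    "name": r.name,
                    "reactants": dict(r.reactants),
                    "products": dict(r.products),
                    "rate_law": {
                        "kind": r.rate_law.kind,
                        **(
                            {"rate_constant": r.rate_law.rate_constant}
                            if r.rate_law.kind == "mass_action"
                            else {
                                "expression": str(parse_expression(r.rate_law.expression)),
                                "parameters": dict(r.rate_law.parameters),
                            }
                        ),
                    },
                }
                for r in self.reactions
            ],
            "conservation_laws": [
                {"coefficients": dict(c), "total": t} for c, t in self.conservation_laws
            ],
            "prefactors": {k: str(v) for k, v in self.prefactors.items()},
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ReactionNetwork":
        species = []
        for s in data["species"]:
            lo, hi = s.get("range", [0.0, None])
            species.append(
                SpeciesSpec(
                    s["name"],
                    s.get("role", "slow"),
                    float(s.get("initial", 0.0)),
                    float(lo),
                    math.inf if hi is None else float(hi),
                )
            )
        reactions = []
        for r in data["reactions"]:
            law = r["rate_law"]
            if law["kind"] == "mass_action":
                rl = RateLaw("mass_action", rate_constant=float(law["rate_constant"]))
            else:
                rl = RateLaw(
                    "closed_form",
                    expression=law["expression"],
                    parameters={k: float(v) for k, v in law.get("parameters", {}).items()},
                )
            reactions.append(
                Reaction(r["name"], dict(r.get("reactants", {})), dict(r.get("products", {})), rl)
            )
        laws = [
            (dict(c["coefficients"]), float(c["total"]))
            for c in data.get("conservation_laws", [])
        ]
        return cls(
            species,
            reactions,
            laws,
            float(data.get("volume", 1.0)),
            prefactors=data.get("prefactors") or None,
            name=data.get("name", "network"),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ReactionNetwork":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def apply_conservation(network: ReactionNetwork) -> ReactionNetwork:
    """Substitute eliminated species out of all rate laws.

    Each species with role ``eliminated`` must appear with nonzero
    coefficient in exactly one conservation law; it is replaced inside every
    rate law by ``(total - sum(coeff*retained))/coeff`` and dropped from the
    species list and stoichiometries.  Networks without eliminated species
    are returned unchanged.
    """
    elim = [s for s in network.species if s.role == "eliminated"]
    if not elim:
        return network
    mapping: dict[str, Expr] = {}
    kept_laws = []
    for coeffs, total in network.conservation_laws:
        targets = [s for s in elim if s.name in coeffs]
        if not targets:
            kept_laws.append((coeffs, total))
            continue
        if len(targets) > 1:
            raise DefinitionError(
                "cannot eliminate two species from one conservation law: "
                + ", ".join(s.name for s in targets)
            )
        target = targets[0]
        c0 = coeffs[target.name]
        if c0 == 0:
            raise DefinitionError(f"zero coefficient for eliminated species {target.name}")
        terms = [repr(float(total))]
        for sp, c in coeffs.items():
            if sp != target.name:
                terms.append(f"- {float(c)!r}*{sp}")
        mapping[target.name] = parse_expression(f"({' '.join(terms)})/{float(c0)!r}")
    missing = [s.name for s in elim if s.name not in mapping]
    if missing:
        raise DefinitionError(f"no conservation law determines {missing}")

    kept = [s for s in network.species if s.role != "eliminated"]
    kept_names = {s.name for s in kept}
    new_reactions = []
    for rxn in network.reactions:
        expr = network.rate_expression(rxn).substitute(mapping)
        new_reactions.append(
            replace(
                rxn,
                reactants={k: v for k, v in rxn.reactants.items() if k in kept_names},
                products={k: v for k, v in rxn.products.items() if k in kept_names},
                rate_law=RateLaw("closed_form", expression=expr)
                if (rxn.rate_law.kind == "closed_form" or (expr.names - kept_names) or
                    set(rxn.reactants) - kept_names or set(rxn.products) - kept_names or
                    mapping.keys() & network.rate_expression(rxn).names)
                else rxn.rate_law,
            )
        )
    return ReactionNetwork(
        kept,
        new_reactions,
        kept_laws,
        network.volume,
        prefactors={k: v for k, v in network.prefactors.items()},
        microscopic_exact=network.microscopic_exact,
        name=network.name,
    )


@dataclass
class ModelPair:
    """A full network, its QSS-reduced counterpart, and the map between them.

    ``slow_map`` sends each slow species of the reduced model to the full
    model species (or, via a custom ``embed``, combination of species) that
    carries it.  ``grid_species`` are the full-model species absent from the
    reduced model -- the fast variables whose entire physical range the
    validation grid spans.  ``qss_map`` sends a reduced slow state to the QSS
    values of the fast species.
    """

    full: ReactionNetwork
    reduced: ReactionNetwork
    slow_map: dict
    observable: str
    grid_species: list[str] = field(default_factory=list)
    qss_map: object = None
    embed: object = None  # callable(slow: dict, fast: dict) -> full initial dict
    fast_constraint: object = None  # callable(fast: dict, slow: dict) -> bool
    name: str = "pair"

    def __post_init__(self):
        red_names = set(self.reduced.species_order)
        full_names = set(self.full.species_order)
        if set(self.slow_map) - red_names:
            raise DefinitionError("slow_map keys must be reduced-model species")
        if self.embed is None and set(self.slow_map.values()) - full_names:
            raise DefinitionError("slow_map values must be full-model species")
        if self.observable not in red_names:
            raise DefinitionError(f"observable {self.observable!r} not in reduced model")

    def reduced_initial(self, slow: dict) -> dict:
        init = self.reduced.initial_state()
        init.update(slow)
        return init

    def full_initial(self, slow: dict, fast: dict) -> dict:
        if self.embed is not None:
            return self.embed(slow, fast)
        init = self.full.initial_state()
        for red_name, value in slow.items():
            init[self.slow_map[red_name]] = value
        init.update(fast)
        return init

    def fast_feasible(self, fast: dict, slow: dict) -> bool:
        if self.fast_constraint is None:
            return True
        return bool(self.fast_constraint(fast, slow))
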