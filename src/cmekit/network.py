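"""Reaction-network definition and validation.

The state of a well-mixed reaction network is the vector of molecule
counts ``x ∈ ℕ₀^{n_s}``.  Each reaction ``j`` carries an integer
state-change vector ``ν_j`` (products minus reactants) and a propensity
``a_j(x, t)``: the probability per unit time that the reaction fires when
the system is in state ``x`` at time ``t``.  Propensities may follow
mass-action kinetics (combinatorial counting of reactant tuples) or be
arbitrary expressions in the species counts, parameters, declared inputs
and time.

Counts are the canonical internal unit.  Each compartment carries a
dimensionless system-size parameter ``Ω`` (its ``volume``); concentrations,
where requested, are counts divided by ``Ω``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import sympy as sp

#: The global time symbol used in propensities, inputs and observables.
TIME = sp.Symbol("t")


def _sym(name: str) -> sp.Symbol:
    return sp.Symbol(name, positive=None)


@dataclass(frozen=True)
class Compartment:
    """A well-mixed volume; ``volume`` is the system-size parameter Ω."""

    name: str
    volume: float = 1.0


@dataclass
class Species:
    name: str
    compartment: str = "default"
    initial_amount: int = 0
    #: hint for the conditional-moment partition: {"low_copy", "high_copy", "auto"}
    abundance_class: str = "auto"

    @property
    def symbol(self) -> sp.Symbol:
        return _sym(self.name)


@dataclass
class Reaction:
    """A single reaction channel.

    ``reactants`` and ``products`` map species names to (positive integer)
    stoichiometric counts.  ``propensity`` is a sympy expression in the
    species symbols, parameters, inputs and ``t``.  ``kinetics`` records
    whether the propensity was generated by the canonical mass-action rule
    or supplied verbatim.  ``delay`` is an optional fixed completion delay:
    the state change ν_j is applied ``delay`` time units after the firing.
    """

    reactants: dict[str, int]
    products: dict[str, int]
    propensity: sp.Expr
    kinetics: str = "general"
    delay: float | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        self.propensity = sp.sympify(self.propensity)
        if self.delay is not None and self.delay < 0:
            raise ValueError("delay must be nonnegative")


def mass_action(rate, reactants: dict[str, int], products: dict[str, int],
                delay: float | None = None, name: str | None = None) -> Reaction:
    """Build a reaction with the canonical mass-action propensity.

    The propensity is ``c · ∏_i binom(x_i, r_i) = c · ∏_i x_i(x_i−1)…(x_i−r_i+1)/r_i!``,
    i.e. ``2X → ·`` fires at ``c·x(x−1)/2``.  The ``r_i!`` division is part of
    the convention; write a general :class:`Reaction` for other choices.
    """
    prop = sp.sympify(rate)
    for name_i, r in reactants.items():
        x = _sym(name_i)
        for k in range(r):
            prop *= (x - k)
        prop /= math.factorial(r)
    return Reaction(dict(reactants), dict(products), sp.expand(prop),
                    kinetics="mass_action", delay=delay, name=name)


@dataclass
class InputSignal:
    """A scalar function of time (and parameters) driving the network."""

    name: str
    expression: sp.Expr

    def __post_init__(self) -> None:
        self.expression = sp.sympify(self.expression)


@dataclass
class Observable:
    name: str
    expression: sp.Expr

    def __post_init__(self) -> None:
        self.expression = sp.sympify(self.expression)


@dataclass
class ReactionNetwork:
    species: list[Species]
    reactions: list[Reaction]
    parameters: dict[str, float] = field(default_factory=dict)
    compartments: list[Compartment] = field(default_factory=lambda: [Compartment("default")])
    inputs: list[InputSignal] = field(default_factory=list)
    observables: list[Observable] = field(default_factory=list)
    name: str = "network"

    # -- structural helpers -------------------------------------------------

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    @property
    def species_symbols(self) -> list[sp.Symbol]:
        return [s.symbol for s in self.species]

    @property
    def parameter_symbols(self) -> list[sp.Symbol]:
        return [_sym(p) for p in self.parameters]

    @property
    def initial_state(self):
        import numpy as np

        return np.array([s.initial_amount for s in self.species], dtype=np.int64)

    def compartment_of(self, species_name: str) -> Compartment:
        comp = {c.name: c for c in self.compartments}
        return comp[next(s for s in self.species if s.name == species_name).compartment]

    def volume_of(self, species_name: str) -> float:
        return self.compartment_of(species_name).volume

    def propensities(self, substitute_inputs: bool = True) -> list[sp.Expr]:
        """Propensity expressions, with input signals inlined by default."""
        props = [r.propensity for r in self.reactions]
        if substitute_inputs and self.inputs:
            subs = {_sym(u.name): u.expression for u in self.inputs}
            props = [p.subs(subs) for p in props]
        return props

    def is_time_dependent(self) -> bool:
        return any(TIME in p.free_symbols for p in self.propensities())

    def declared_symbols(self) -> set[sp.Symbol]:
        syms = {TIME}
        syms.update(self.species_symbols)
        syms.update(self.parameter_symbols)
        syms.update(_sym(u.name) for u in self.inputs)
        return syms


def stoichiometry_matrix(net: ReactionNetwork):
    """The n_s × n_r matrix whose column j is the state change ν_j."""
    import numpy as np

    S = np.zeros((net.n_species, net.n_reactions), dtype=np.int64)
    index = {name: i for i, name in enumerate(net.species_names)}
    for j, r in enumerate(net.reactions):
        for name, count in r.reactants.items():
            S[index[name], j] -= count
        for name, count in r.products.items():
            S[index[name], j] += count
    return S


def validate_network(net: ReactionNetwork) -> list[str]:
    """Check all type invariants; returns one diagnostic string per violation.

    An empty list means the network is well formed.  Violations do not raise:
    downstream engines call this and refuse invalid networks themselves.
    """
    diags: list[str] = []
    seen: set[str] = set()
    comp_names = {c.name for c in net.compartments}
    for c in net.compartments:
        if c.volume <= 0:
            diags.append(f"compartment '{c.name}' has non-positive volume {c.volume}")
    if len(comp_names) != len(net.compartments):
        diags.append("compartment names are not unique")
    for s in net.species:
        if s.name in seen:
            diags.append(f"duplicate species name '{s.name}'")
        seen.add(s.name)
        if s.compartment not in comp_names:
            diags.append(f"species '{s.name}' references unknown compartment '{s.compartment}'")
        if s.initial_amount < 0:
            diags.append(f"species '{s.name}' has negative initial amount {s.initial_amount}")
        if int(s.initial_amount) != s.initial_amount:
            diags.append(f"species '{s.name}' has non-integer initial amount {s.initial_amount}")
    if net.n_species < 1:
        diags.append("network has no species")
    if net.n_reactions < 1:
        diags.append("network has no reactions")

    declared = net.declared_symbols()
    species_set = set(net.species_names)
    for j, r in enumerate(net.reactions):
        label = r.name or f"reaction {j}"
        for name, count in {**r.reactants, **r.products}.items():
            if name not in species_set:
                diags.append(f"{label} references undeclared species '{name}'")
            if int(count) != count:
                diags.append(f"{label} has non-integer stoichiometry for '{name}'")
        for sym in r.propensity.free_symbols - declared:
            diags.append(f"{label} propensity references undeclared symbol '{sym}'")
        if r.delay is not None and r.delay < 0:
            diags.append(f"{label} has negative delay {r.delay}")
    for o in net.observables:
        for sym in o.expression.free_symbols - declared:
            diags.append(f"observable '{o.name}' references undeclared symbol '{sym}'")
    for u in net.inputs:
        extra = u.expression.free_symbols - {TIME} - set(net.parameter_symbols)
        for sym in extra:
            diags.append(f"input '{u.name}' references undeclared symbol '{sym}'")
    return diags
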