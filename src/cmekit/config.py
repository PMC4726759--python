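"""Native declarative network definition (YAML or JSON).

Schema (all sections except ``species`` and ``reactions`` optional)::

    name: birth_death
    compartments:
      - {name: default, volume: 1.0}
    species:
      - {name: X, compartment: default, initial_amount: 0, abundance_class: auto}
    parameters: {k: 10.0, gamma: 1.0}
    reactions:
      - name: birth
        reactants: {}
        products: {X: 1}
        propensity: "k"
      - name: death
        reactants: {X: 1}
        products: {}
        propensity: "gamma*X"
        delay: 0.0            # optional
    inputs:
      - {name: u, expression: "exp(-t/5)"}
    observables:
      - {name: X_count, expression: "X"}

Propensity/observable/input expressions are parsed by sympy; ``t`` denotes
time.  :func:`save_network` writes the same schema, so load∘save is the
identity.  A machine-readable JSON Schema is shipped alongside
(``network.schema.json``).
"""

from __future__ import annotations

import json
from pathlib import Path

import sympy as sp
import yaml

from .network import (
    Compartment,
    InputSignal,
    Observable,
    Reaction,
    ReactionNetwork,
    Species,
)

SCHEMA_PATH = Path(__file__).parent / "network.schema.json"


def load_network(path) -> ReactionNetwork:
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    return network_from_dict(doc)


def network_from_dict(doc: dict) -> ReactionNetwork:
    compartments = [Compartment(c["name"], float(c.get("volume", 1.0)))
                    for c in doc.get("compartments", [{"name": "default"}])]
    species = [Species(s["name"], s.get("compartment", compartments[0].name),
                       int(s.get("initial_amount", 0)),
                       s.get("abundance_class", "auto"))
               for s in doc["species"]]
    # explicit symbol table: declared names always parse as plain symbols
    # (sympify alone would read a species called "S" as sympy's singleton)
    table = {s.name: sp.Symbol(s.name) for s in species}
    table.update({name: sp.Symbol(name) for name in (doc.get("parameters") or {})})
    table.update({u["name"]: sp.Symbol(u["name"]) for u in doc.get("inputs", [])})
    table["t"] = sp.Symbol("t")

    def parse(expr: str):
        return sp.parse_expr(str(expr), local_dict=table)

    reactions = []
    for r in doc["reactions"]:
        reactions.append(Reaction(
            {k: int(v) for k, v in (r.get("reactants") or {}).items()},
            {k: int(v) for k, v in (r.get("products") or {}).items()},
            parse(r["propensity"]),
            kinetics=r.get("kinetics", "general"),
            delay=r.get("delay"),
            name=r.get("name")))
    inputs = [InputSignal(u["name"], parse(u["expression"]))
              for u in doc.get("inputs", [])]
    observables = [Observable(o["name"], parse(o["expression"]))
                   for o in doc.get("observables", [])]
    return ReactionNetwork(
        species=species, reactions=reactions,
        parameters={k: float(v) for k, v in (doc.get("parameters") or {}).items()},
        compartments=compartments, inputs=inputs, observables=observables,
        name=doc.get("name", "network"))


def network_to_dict(net: ReactionNetwork) -> dict:
    return {
        "name": net.name,
        "compartments": [{"name": c.name, "volume": c.volume}
                         for c in net.compartments],
        "species": [{"name": s.name, "compartment": s.compartment,
                     "initial_amount": int(s.initial_amount),
                     "abundance_class": s.abundance_class}
                    for s in net.species],
        "parameters": {k: float(v) for k, v in net.parameters.items()},
        "reactions": [{
            "name": r.name, "reactants": dict(r.reactants),
            "products": dict(r.products), "propensity": str(r.propensity),
            "kinetics": r.kinetics,
            **({"delay": r.delay} if r.delay is not None else {})}
            for r in net.reactions],
        "inputs": [{"name": u.name, "expression": str(u.expression)}
                   for u in net.inputs],
        "observables": [{"name": o.name, "expression": str(o.expression)}
                        for o in net.observables],
    }


def save_network(net: ReactionNetwork, path) -> None:
    path = Path(path)
    doc = network_to_dict(net)
    with open(path, "w") as fh:
        if path.suffix == ".json":
            json.dump(doc, fh, indent=2)
        else:
            yaml.safe_dump(doc, fh, sort_keys=False)
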