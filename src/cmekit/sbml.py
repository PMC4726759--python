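"""SBML import and export for reaction networks.

Reads the SBML Level 2/3 core subset that maps onto this package's model
class: compartments, species, global and reaction-local parameters, and
reactions with kinetic-law MathML.  Kinetic laws become general
propensities; reversible reactions are split into two irreversible
reactions with opposite stoichiometry by separating the positive and
negated terms of the expanded rate law; reaction-local parameters are
promoted to global parameters under reaction-prefixed names so that the
parameter vector stays flat.  Species amounts are converted to integer
counts (``initialConcentration`` is multiplied by the compartment size;
non-integer amounts are rounded with a warning).

Events, assignment/rate rules, function definitions and hierarchical
models are out of scope; a reaction without a kinetic law is rejected.
The exporter writes the same subset (content MathML emitted by sympy), so
export→import is an identity up to these conventions.
"""

from __future__ import annotations

import warnings

import sympy as sp
from lxml import etree

from .network import TIME, Compartment, Reaction, ReactionNetwork, Species

SBML_L3_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
_TIME_CSYMBOL = "http://www.sbml.org/sbml/symbols/time"


class SBMLFormatError(ValueError):
    pass


class SBMLUnsupportedError(ValueError):
    pass


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


# ---------------------------------------------------------------------------
# content MathML -> sympy
# ---------------------------------------------------------------------------

_MATHML_OPS = {
    "plus": lambda *a: sp.Add(*a),
    "times": lambda *a: sp.Mul(*a),
    "minus": lambda *a: a[0] - a[1] if len(a) == 2 else -a[0],
    "divide": lambda x, y: x / y,
    "power": lambda x, y: x ** y,
    "exp": sp.exp,
    "ln": sp.log,
    "log": sp.log,
    "sin": sp.sin,
    "cos": sp.cos,
    "tan": sp.tan,
    "root": lambda x: sp.sqrt(x),
    "abs": sp.Abs,
}


def _parse_mathml(node) -> sp.Expr:
    tag = _local(node.tag)
    if tag == "math":
        children = [c for c in node if isinstance(c.tag, str)]
        if len(children) != 1:
            raise SBMLFormatError("math element must have exactly one child")
        return _parse_mathml(children[0])
    if tag == "ci":
        return sp.Symbol(node.text.strip())
    if tag == "csymbol":
        if node.get("definitionURL", "").endswith("time"):
            return TIME
        raise SBMLUnsupportedError(f"unsupported csymbol '{node.get('definitionURL')}'")
    if tag == "cn":
        ctype = node.get("type", "real")
        if ctype in ("integer", "real", None, "", "rational", "e-notation"):
            text = (node.text or "").strip()
            if ctype == "integer":
                return sp.Integer(int(text))
            parts = [t for t in node.itertext()]
            if ctype == "rational":
                nums = "".join(parts).split()
                return sp.Rational(int(nums[0]), int(nums[1]))
            if ctype == "e-notation":
                nums = "".join(parts).split()
                return sp.Float(float(nums[0]) * 10 ** float(nums[1]))
            return sp.Float(float(text))
        raise SBMLUnsupportedError(f"unsupported cn type '{ctype}'")
    if tag == "apply":
        children = [c for c in node if isinstance(c.tag, str)]
        op = _local(children[0].tag)
        args = [_parse_mathml(c) for c in children[1:]]
        if op == "ci":  # user function application — unsupported
            raise SBMLUnsupportedError("function definitions are not supported")
        if op not in _MATHML_OPS:
            raise SBMLUnsupportedError(f"unsupported MathML operator '{op}'")
        return _MATHML_OPS[op](*args)
    if tag in ("pi",):
        return sp.pi
    if tag in ("exponentiale",):
        return sp.E
    raise SBMLUnsupportedError(f"unsupported MathML element '{tag}'")


# ---------------------------------------------------------------------------
# import
# ---------------------------------------------------------------------------

def import_sbml(path) -> ReactionNetwork:
    """Read an SBML file into a :class:`ReactionNetwork` (counts-based)."""
    try:
        tree = etree.parse(str(path))
    except (etree.XMLSyntaxError, OSError) as exc:
        raise SBMLFormatError(f"cannot parse SBML file {path}: {exc}") from exc
    root = tree.getroot()
    if _local(root.tag) != "sbml":
        raise SBMLFormatError(f"root element is '{_local(root.tag)}', expected 'sbml'")
    model = next((c for c in root if _local(c.tag) == "model"), None)
    if model is None:
        raise SBMLFormatError("no <model> element found")

    def children_of(list_tag):
        lst = next((c for c in model if _local(c.tag) == list_tag), None)
        return [c for c in lst if isinstance(c.tag, str)] if lst is not None else []

    compartments = []
    comp_size = {}
    for c in children_of("listOfCompartments"):
        size = float(c.get("size", c.get("volume", 1.0)) or 1.0)
        compartments.append(Compartment(c.get("id"), size))
        comp_size[c.get("id")] = size
    if not compartments:
        compartments = [Compartment("default", 1.0)]
        comp_size["default"] = 1.0

    species = []
    for s in children_of("listOfSpecies"):
        sid = s.get("id")
        comp = s.get("compartment", compartments[0].name)
        if s.get("initialAmount") is not None:
            amount = float(s.get("initialAmount"))
        elif s.get("initialConcentration") is not None:
            amount = float(s.get("initialConcentration")) * comp_size.get(comp, 1.0)
        else:
            amount = 0.0
        rounded = round(amount)
        if abs(rounded - amount) > 1e-9:
            warnings.warn(
                f"species '{sid}': non-integer amount {amount} rounded to {rounded}")
        species.append(Species(sid, comp, int(rounded)))

    parameters = {}
    for p in children_of("listOfParameters"):
        parameters[p.get("id")] = float(p.get("value", 0.0) or 0.0)

    reactions = []
    for rx in children_of("listOfReactions"):
        rid = rx.get("id") or f"r{len(reactions)}"
        reversible = (rx.get("reversible", "false").lower() == "true")

        def refs(tag):
            lst = next((c for c in rx if _local(c.tag) == tag), None)
            out = {}
            if lst is not None:
                for ref in lst:
                    if isinstance(ref.tag, str):
                        out[ref.get("species")] = int(float(ref.get("stoichiometry", 1)))
            return out

        reactants = refs("listOfReactants")
        products = refs("listOfProducts")
        klaw = next((c for c in rx if _local(c.tag) == "kineticLaw"), None)
        if klaw is None:
            raise SBMLUnsupportedError(f"reaction '{rid}' has no kineticLaw")
        math_el = next((c for c in klaw if _local(c.tag) == "math"), None)
        if math_el is None:
            raise SBMLUnsupportedError(f"reaction '{rid}' kineticLaw has no math")
        rate = _parse_mathml(math_el)
        # promote local parameters with reaction-prefixed names
        for lp_list in ("listOfLocalParameters", "listOfParameters"):
            lst = next((c for c in klaw if _local(c.tag) == lp_list), None)
            if lst is not None:
                for lp in lst:
                    if isinstance(lp.tag, str):
                        lid = lp.get("id")
                        new = f"{rid}_{lid}"
                        parameters[new] = float(lp.get("value", 0.0) or 0.0)
                        rate = rate.subs(sp.Symbol(lid), sp.Symbol(new))
        # compartment sizes referenced by id become numeric factors
        for cname, size in comp_size.items():
            rate = rate.subs(sp.Symbol(cname), sp.Float(size))

        if reversible:
            fwd, bwd = _split_reversible(rate)
            reactions.append(Reaction(reactants, products, fwd, name=rid + "_fwd"))
            reactions.append(Reaction(products, reactants, bwd, name=rid + "_rev"))
        else:
            reactions.append(Reaction(reactants, products, rate, name=rid))

    return ReactionNetwork(species=species, reactions=reactions,
                           parameters=parameters, compartments=compartments,
                           name=model.get("id", "sbml_model"))


def _split_reversible(rate: sp.Expr):
    """Split an expanded net rate into forward (positive) and backward
    (negated negative) parts; a one-signed law gets a zero reverse rate."""
    pos, neg = sp.Integer(0), sp.Integer(0)
    for term in sp.Add.make_args(sp.expand(rate)):
        if term.could_extract_minus_sign():
            neg += -term
        else:
            pos += term
    return pos, neg


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def _to_mathml(expr: sp.Expr):
    """Content MathML element for a sympy expression.

    Symbols are printed through ASCII placeholders because sympy's MathML
    printer renders names like ``gamma`` as Greek glyphs, which would not
    round-trip.
    """
    expr = sp.sympify(expr).subs(TIME, sp.Symbol("__time__"))
    placeholders = {}
    for i, s in enumerate(sorted(expr.free_symbols, key=str)):
        placeholders[s] = sp.Symbol(f"cmekitsym{i}x")
    xml = sp.mathml(expr.subs(placeholders, simultaneous=True), printer="content")
    for s, ph in placeholders.items():
        xml = xml.replace(f"<ci>{ph}</ci>", f"<ci>{s}</ci>")
    xml = xml.replace(
        "<ci>__time__</ci>",
        f'<csymbol encoding="text" definitionURL="{_TIME_CSYMBOL}">t</csymbol>')
    wrapped = f'<math xmlns="{MATHML_NS}">{xml}</math>'
    return etree.fromstring(wrapped.encode())


def export_sbml(net: ReactionNetwork, path) -> None:
    """Write the network as SBML Level 3 (irreversible reactions only)."""
    nsmap = {None: SBML_L3_NS}
    root = etree.Element("sbml", nsmap=nsmap, level="3", version="2")
    model = etree.SubElement(root, "model", id=net.name or "model")

    lc = etree.SubElement(model, "listOfCompartments")
    for c in net.compartments:
        etree.SubElement(lc, "compartment", id=c.name, size=repr(float(c.volume)),
                         constant="true")
    ls = etree.SubElement(model, "listOfSpecies")
    for s in net.species:
        etree.SubElement(ls, "species", id=s.name, compartment=s.compartment,
                         initialAmount=repr(float(s.initial_amount)),
                         hasOnlySubstanceUnits="true", boundaryCondition="false",
                         constant="false")
    lp = etree.SubElement(model, "listOfParameters")
    for name, value in net.parameters.items():
        etree.SubElement(lp, "parameter", id=name, value=repr(float(value)),
                         constant="true")
    lr = etree.SubElement(model, "listOfReactions")
    inputs = {sp.Symbol(u.name): u.expression for u in net.inputs}
    for j, r in enumerate(net.reactions):
        rx = etree.SubElement(lr, "reaction", id=r.name or f"r{j}",
                              reversible="false")
        if r.reactants:
            lrt = etree.SubElement(rx, "listOfReactants")
            for nm, count in r.reactants.items():
                etree.SubElement(lrt, "speciesReference", species=nm,
                                 stoichiometry=str(count), constant="true")
        if r.products:
            lpr = etree.SubElement(rx, "listOfProducts")
            for nm, count in r.products.items():
                etree.SubElement(lpr, "speciesReference", species=nm,
                                 stoichiometry=str(count), constant="true")
        klaw = etree.SubElement(rx, "kineticLaw")
        prop = sp.sympify(r.propensity).subs(inputs, simultaneous=True)
        klaw.append(_to_mathml(prop))
    etree.ElementTree(root).write(str(path), pretty_print=True,
                                  xml_declaration=True, encoding="UTF-8")
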