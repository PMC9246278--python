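"""SBML Level 3 Version 2 (core) serialisation of the model.

The exporter writes the subset of SBML the model needs — compartment,
species with initial amounts, constant parameters, irreversible reactions
with content-MathML kinetic laws — and the importer reads exactly that
subset back (plus plain L2/L3 files restricted to it).  The three input
signals (FUS3, HOG1, NU) are exported as non-constant parameters; switching
them over time is run configuration, not part of the model document.

Conservation pools, species roles and the production-parameter subset are
round-tripped through machine-readable ``notes`` elements.
"""

from __future__ import annotations

import sympy
from lxml import etree

from .model_core import (
    ModelDefinition,
    ParameterSet,
    Reaction,
    SpeciesInventory,
    SpeciesRecord,
)

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"
XHTML_NS = "http://www.w3.org/1999/xhtml"

# SBML IDs in third-party documents that differ from the native names
SPECIES_ALIASES: dict[str, str] = {}

_SIGNALS = ("FUS3", "HOG1", "NU")
_SIGNAL_DEFAULTS = {"FUS3": 0.0, "HOG1": 0.0, "NU": 1.0}


class SBMLError(ValueError):
    """Unreadable or unsupported SBML content."""


# --- expression <-> content MathML ------------------------------------------

def _expr_to_mathml(expr: sympy.Expr, parent: etree._Element) -> None:
    E = lambda tag: etree.SubElement(parent, f"{{{MATHML_NS}}}{tag}")

    def emit(node, parent):
        sub = lambda tag: etree.SubElement(parent, f"{{{MATHML_NS}}}{tag}")
        if isinstance(node, sympy.Symbol):
            sub("ci").text = f" {node.name} "
        elif isinstance(node, (sympy.Integer, sympy.Float)):
            sub("cn").text = f" {float(node):.17g} "
        elif isinstance(node, sympy.Rational):
            apply_ = sub("apply")
            etree.SubElement(apply_, f"{{{MATHML_NS}}}divide")
            emit(sympy.Integer(node.p), apply_)
            emit(sympy.Integer(node.q), apply_)
        elif isinstance(node, sympy.Add):
            apply_ = sub("apply")
            etree.SubElement(apply_, f"{{{MATHML_NS}}}plus")
            for arg in node.args:
                emit(arg, apply_)
        elif isinstance(node, sympy.Mul):
            num, den = node.as_numer_denom()
            if den != 1:
                apply_ = sub("apply")
                etree.SubElement(apply_, f"{{{MATHML_NS}}}divide")
                emit(num, apply_)
                emit(den, apply_)
            else:
                apply_ = sub("apply")
                etree.SubElement(apply_, f"{{{MATHML_NS}}}times")
                for arg in node.args:
                    emit(arg, apply_)
        elif isinstance(node, sympy.Pow):
            base, exponent = node.args
            if exponent == -1:
                apply_ = sub("apply")
                etree.SubElement(apply_, f"{{{MATHML_NS}}}divide")
                emit(sympy.Integer(1), apply_)
                emit(base, apply_)
            elif exponent.is_negative:
                apply_ = sub("apply")
                etree.SubElement(apply_, f"{{{MATHML_NS}}}divide")
                emit(sympy.Integer(1), apply_)
                emit(sympy.Pow(base, -exponent), apply_)
            else:
                apply_ = sub("apply")
                etree.SubElement(apply_, f"{{{MATHML_NS}}}power")
                emit(base, apply_)
                emit(exponent, apply_)
        else:
            raise SBMLError(f"cannot serialise expression node {node!r}")

    emit(expr, parent)


def _mathml_to_expr_str(element: etree._Element) -> str:
    tag = etree.QName(element).localname
    if tag == "math":
        children = [c for c in element if isinstance(c.tag, str)]
        if len(children) != 1:
            raise SBMLError("math element must have exactly one child")
        return _mathml_to_expr_str(children[0])
    if tag == "ci":
        return element.text.strip()
    if tag == "cn":
        return repr(float(element.text.strip()))
    if tag == "apply":
        children = [c for c in element if isinstance(c.tag, str)]
        op = etree.QName(children[0]).localname
        args = [_mathml_to_expr_str(c) for c in children[1:]]
        if op == "plus":
            return "(" + " + ".join(args) + ")"
        if op == "times":
            return "(" + " * ".join(args) + ")"
        if op == "minus":
            if len(args) == 1:
                return f"(-{args[0]})"
            return f"({args[0]} - {args[1]})"
        if op == "divide":
            return f"({args[0]} / {args[1]})"
        if op == "power":
            return f"({args[0]} ** {args[1]})"
        raise SBMLError(f"unsupported MathML operator <{op}>")
    raise SBMLError(f"unsupported MathML element <{tag}> at {element.getroottree().getpath(element)}")


def _notes(parent: etree._Element, lines: list[str]) -> None:
    notes = etree.SubElement(parent, f"{{{SBML_NS}}}notes")
    body = etree.SubElement(notes, f"{{{XHTML_NS}}}body")
    for line in lines:
        p = etree.SubElement(body, f"{{{XHTML_NS}}}p")
        p.text = line


def _read_notes(element: etree._Element) -> list[str]:
    out = []
    for p in element.iterfind(f"./{{{SBML_NS}}}notes//{{{XHTML_NS}}}p"):
        if p.text:
            out.append(p.text.strip())
    return out


# --- export ------------------------------------------------------------------

def export_sbml(model: ModelDefinition, path=None) -> bytes:
    """Serialise ``model`` to an SBML L3V2 document.

    Returns the document bytes; additionally writes them to ``path`` when
    given.  Conservation pools and the production-parameter subset are
    recorded as model notes so the document round-trips completely.
    """
    root = etree.Element(f"{{{SBML_NS}}}sbml",
                         nsmap={None: SBML_NS},
                         level="3", version="2")
    mdl = etree.SubElement(root, f"{{{SBML_NS}}}model",
                           id="yeast_cell_cycle", name="Yeast cell cycle ODE model",
                           substanceUnits="item", timeUnits="second",
                           extentUnits="item")
    note_lines = ["units: particle numbers (molecules/cell), time in minutes"]
    for pool, members in model.conservation_pools.items():
        note_lines.append(f"pool:{pool}=" + ",".join(members))
    note_lines.append("production:" + ",".join(sorted(model.parameters.production_subset)))
    _notes(mdl, note_lines)

    comps = etree.SubElement(mdl, f"{{{SBML_NS}}}listOfCompartments")
    etree.SubElement(comps, f"{{{SBML_NS}}}compartment", id="cell",
                     spatialDimensions="3", size="1", constant="true")

    species_list = etree.SubElement(mdl, f"{{{SBML_NS}}}listOfSpecies")
    for entry, amount in zip(model.inventory.entries, model.initial_state):
        sp = etree.SubElement(
            species_list, f"{{{SBML_NS}}}species", id=entry.name,
            compartment="cell", initialAmount=f"{amount:.17g}",
            hasOnlySubstanceUnits="true", boundaryCondition="false",
            constant="false")
        lines = [f"role:{entry.role}"]
        if entry.pools:
            lines.append("pools:" + ",".join(entry.pools))
        if entry.constituents:
            lines.append("constituents:" + ",".join(entry.constituents))
        _notes(sp, lines)

    params_list = etree.SubElement(mdl, f"{{{SBML_NS}}}listOfParameters")
    for name in model.parameter_order:
        etree.SubElement(params_list, f"{{{SBML_NS}}}parameter", id=name,
                         value=f"{model.parameters[name]:.17g}", constant="true")
    for signal in _SIGNALS:
        etree.SubElement(params_list, f"{{{SBML_NS}}}parameter", id=signal,
                         value=f"{_SIGNAL_DEFAULTS[signal]:.17g}",
                         constant="false")

    reactions_list = etree.SubElement(mdl, f"{{{SBML_NS}}}listOfReactions")
    for reaction in model.rate_laws:
        rx = etree.SubElement(reactions_list, f"{{{SBML_NS}}}reaction",
                              id=reaction.name, reversible="false")
        reactants = [(s, -c) for s, c in reaction.stoichiometry.items() if c < 0]
        products = [(s, c) for s, c in reaction.stoichiometry.items() if c > 0]
        if reactants:
            lst = etree.SubElement(rx, f"{{{SBML_NS}}}listOfReactants")
            for sp, coeff in reactants:
                etree.SubElement(lst, f"{{{SBML_NS}}}speciesReference",
                                 species=sp, stoichiometry=str(coeff),
                                 constant="true")
        if products:
            lst = etree.SubElement(rx, f"{{{SBML_NS}}}listOfProducts")
            for sp, coeff in products:
                etree.SubElement(lst, f"{{{SBML_NS}}}speciesReference",
                                 species=sp, stoichiometry=str(coeff),
                                 constant="true")
        law = etree.SubElement(rx, f"{{{SBML_NS}}}kineticLaw")
        math = etree.SubElement(law, f"{{{MATHML_NS}}}math",
                                nsmap={None: MATHML_NS})
        expr = sympy.parse_expr(reaction.rate)
        _expr_to_mathml(expr, math)

    data = etree.tostring(root, xml_declaration=True, encoding="UTF-8",
                          pretty_print=True)
    if path is not None:
        with open(path, "wb") as handle:
            handle.write(data)
    return data


# --- import ------------------------------------------------------------------

def import_sbml(source) -> ModelDefinition:
    """Read an SBML document (path or bytes) into a :class:`ModelDefinition`.

    Supports the L3 (and compatible L2) core subset this package exports:
    species with initial amounts, parameters, irreversible reactions with
    kinetic-law math over species, parameters and the three input signals.
    Unsupported constructs raise :class:`SBMLError` naming the element.
    """
    try:
        if isinstance(source, (bytes, bytearray)):
            root = etree.fromstring(bytes(source))
        else:
            root = etree.parse(str(source)).getroot()
    except etree.XMLSyntaxError as exc:
        raise SBMLError(f"invalid XML: {exc}") from exc
    ns = etree.QName(root).namespace
    if ns is None or "sbml.org/sbml" not in ns:
        raise SBMLError("not an SBML document")

    def q(tag):
        return f"{{{ns}}}{tag}"

    mdl = root.find(q("model"))
    if mdl is None:
        raise SBMLError("missing <model> element")

    for unsupported in ("listOfRules", "listOfEvents", "listOfConstraints",
                        "listOfFunctionDefinitions", "listOfInitialAssignments"):
        if mdl.find(q(unsupported)) is not None:
            raise SBMLError(f"unsupported SBML construct <{unsupported}>")

    pools: dict[str, tuple[str, ...]] = {}
    production: set[str] = set()
    for line in _read_notes(mdl):
        if line.startswith("pool:"):
            pool, members = line[len("pool:"):].split("=", 1)
            pools[pool] = tuple(members.split(","))
        elif line.startswith("production:"):
            production = set(line[len("production:"):].split(","))

    entries = []
    initial = []
    for sp in mdl.iterfind(f"{q('listOfSpecies')}/{q('species')}"):
        sid = SPECIES_ALIASES.get(sp.get("id"), sp.get("id"))
        amount = sp.get("initialAmount")
        if amount is None:
            raise SBMLError(f"species {sid} has no initialAmount")
        role, sp_pools, constituents = "complex", (), ()
        for line in _read_notes(sp):
            if line.startswith("role:"):
                role = line[len("role:"):]
            elif line.startswith("pools:"):
                sp_pools = tuple(line[len("pools:"):].split(","))
            elif line.startswith("constituents:"):
                constituents = tuple(line[len("constituents:"):].split(","))
        entries.append(SpeciesRecord(sid, role, sp_pools, constituents))
        initial.append(float(amount))
    if not entries:
        raise SBMLError("document contains no species")

    values = {}
    for par in mdl.iterfind(f"{q('listOfParameters')}/{q('parameter')}"):
        pid = par.get("id")
        if pid in _SIGNALS:
            continue
        values[pid] = float(par.get("value"))
    if not production:
        production = {p for p in values if p.startswith("ks_")}

    species_names = {e.name for e in entries}
    reactions = []
    for rx in mdl.iterfind(f"{q('listOfReactions')}/{q('reaction')}"):
        stoich: dict[str, int] = {}
        for ref in rx.iterfind(f"{q('listOfReactants')}/{q('speciesReference')}"):
            sid = SPECIES_ALIASES.get(ref.get("species"), ref.get("species"))
            stoich[sid] = stoich.get(sid, 0) - int(float(ref.get("stoichiometry", "1")))
        for ref in rx.iterfind(f"{q('listOfProducts')}/{q('speciesReference')}"):
            sid = SPECIES_ALIASES.get(ref.get("species"), ref.get("species"))
            stoich[sid] = stoich.get(sid, 0) + int(float(ref.get("stoichiometry", "1")))
        unmapped = sorted(set(stoich) - species_names)
        if unmapped:
            raise SBMLError(f"reaction {rx.get('id')} references unmapped "
                            f"species: {unmapped}")
        law = rx.find(q("kineticLaw"))
        if law is None:
            raise SBMLError(f"reaction {rx.get('id')} has no kineticLaw")
        math = law.find(f"{{{MATHML_NS}}}math")
        if math is None:
            raise SBMLError(f"reaction {rx.get('id')} kineticLaw has no math")
        expr = _mathml_to_expr_str(math)
        reactions.append(Reaction(rx.get("id"), stoich, expr))

    return ModelDefinition(
        inventory=SpeciesInventory(tuple(entries)),
        parameters=ParameterSet(values, frozenset(production & set(values))),
        rate_laws=tuple(reactions),
        conservation_pools=pools,
        initial_state=initial,
    )


def structural_report(source) -> dict:
    """Species/parameter/reaction counts of an SBML document."""
    model = import_sbml(source)
    return {
        "n_species": model.n_species,
        "n_parameters": model.n_parameters,
        "n_reactions": len(model.rate_laws),
        "pools": {k: list(v) for k, v in model.conservation_pools.items()},
    }
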