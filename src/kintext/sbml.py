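"""SBML Level 3 Version 2 serialization, structural validation, and reading.

The writer produces a complete, self-contained L3V2 Core document: one
compartment of size 1, fully attributed species (initial concentration,
``hasOnlySubstanceUnits``, ``boundaryCondition``, ``constant``), global
parameters, and reactions with reactant/product/modifier lists and content
MathML kinetic laws. The validator implements a fixed structural subset of
the SBML consistency rules — well-formedness, required attributes, declared
references, unique and grammatical SIds, defined initial state, and the
presence of kinetic laws. A document with at least one error-severity issue
is invalid. This is precisely the failure surface on which free-form
generated SBML tends to break (missing required attributes chief among
them).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import sympy as sp
from lxml import etree

from .builder import KineticModel, Parameter, RateLaw, Reaction, Species
from .errors import ValidationError
from .ir import SpeciesRef

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"

# issue codes
MALFORMED_XML = "MALFORMED_XML"
MISSING_REQUIRED_ATTRIBUTE = "MISSING_REQUIRED_ATTRIBUTE"
UNDECLARED_SPECIES = "UNDECLARED_SPECIES"
DUPLICATE_ID = "DUPLICATE_ID"
NO_INITIAL_STATE = "NO_INITIAL_STATE"
INVALID_SID = "INVALID_SID"
MISSING_KINETIC_LAW = "MISSING_KINETIC_LAW"

_SID_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_]*\Z")

#: Required attributes per SBML L3V2 Core element (the structural subset).
REQUIRED_ATTRIBUTES = {
    "sbml": ("level", "version"),
    "compartment": ("id", "constant"),
    "species": ("id", "compartment", "hasOnlySubstanceUnits",
                "boundaryCondition", "constant"),
    "parameter": ("id", "constant"),
    "reaction": ("id", "reversible"),
    "speciesReference": ("species", "constant"),
    "modifierSpeciesReference": ("species",),
}


@dataclass(frozen=True)
class SBMLIssue:
    severity: str  # "error" | "warning"
    code: str
    message: str
    location: str

    def __str__(self) -> str:
        return f"[{self.severity}] {self.code} at {self.location}: {self.message}"


# ---------------------------------------------------------------------------
# MathML <-> sympy

def _number_to_mathml(x) -> etree._Element:
    cn = etree.Element(f"{{{MATHML_NS}}}cn")
    if isinstance(x, sp.Integer) or float(x).is_integer():
        cn.set("type", "integer")
        cn.text = str(int(x))
    else:
        cn.text = repr(float(x))
    return cn


def _apply(op: str, *children) -> etree._Element:
    node = etree.Element(f"{{{MATHML_NS}}}apply")
    node.append(etree.Element(f"{{{MATHML_NS}}}{op}"))
    for c in children:
        node.append(c)
    return node


def expression_to_mathml(expr: sp.Expr) -> etree._Element:
    """Content-MathML element for a rate expression."""
    if isinstance(expr, sp.Symbol):
        ci = etree.Element(f"{{{MATHML_NS}}}ci")
        ci.text = expr.name
        return ci
    if expr.is_Number:
        if isinstance(expr, sp.Rational) and not isinstance(expr, sp.Integer):
            return _apply("divide", _number_to_mathml(sp.Integer(expr.p)),
                          _number_to_mathml(sp.Integer(expr.q)))
        return _number_to_mathml(expr)
    num, den = sp.fraction(sp.together(expr))
    if den != 1:
        return _apply("divide", expression_to_mathml(num), expression_to_mathml(den))
    if isinstance(expr, sp.Add):
        return _apply("plus", *[expression_to_mathml(a) for a in expr.args])
    if isinstance(expr, sp.Mul):
        return _apply("times", *[expression_to_mathml(a) for a in expr.args])
    if isinstance(expr, sp.Pow):
        return _apply("power", expression_to_mathml(expr.base),
                      expression_to_mathml(expr.exp))
    raise ValueError(f"cannot serialize expression node {expr!r} as MathML")


_MATHML_OPS = {
    "plus": lambda args: sp.Add(*args),
    "times": lambda args: sp.Mul(*args),
    "divide": lambda args: args[0] / args[1],
    "power": lambda args: args[0] ** args[1],
    "minus": lambda args: -args[0] if len(args) == 1 else args[0] - args[1],
}


def mathml_to_expression(node: etree._Element) -> sp.Expr:
    """Inverse of :func:`expression_to_mathml` (plus/minus/times/divide/power)."""
    tag = etree.QName(node).localname
    if tag == "math":
        children = list(node)
        if len(children) != 1:
            raise ValidationError([SBMLIssue("error", MALFORMED_XML,
                                             "math element must have one child", "math")])
        return mathml_to_expression(children[0])
    if tag == "ci":
        return sp.Symbol(node.text.strip())
    if tag == "cn":
        text = node.text.strip()
        if node.get("type") == "integer" or re.fullmatch(r"-?\d+", text):
            return sp.Integer(int(text))
        return sp.Float(text)
    if tag == "apply":
        children = list(node)
        op = etree.QName(children[0]).localname
        if op not in _MATHML_OPS:
            raise ValueError(f"unsupported MathML operator {op!r}")
        args = [mathml_to_expression(c) for c in children[1:]]
        return _MATHML_OPS[op](args)
    raise ValueError(f"unsupported MathML element {tag!r}")


# ---------------------------------------------------------------------------
# writer

def _format_number(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


def write_sbml(model: KineticModel) -> str:
    """Serialize a model as an SBML L3V2 XML document (UTF-8 text)."""
    model.validate()
    nsmap = {None: SBML_NS}
    root = etree.Element(f"{{{SBML_NS}}}sbml", nsmap=nsmap)
    root.set("level", "3")
    root.set("version", "2")
    mel = etree.SubElement(root, f"{{{SBML_NS}}}model")
    mel.set("id", model.name)

    locs = etree.SubElement(mel, f"{{{SBML_NS}}}listOfCompartments")
    comp = etree.SubElement(locs, f"{{{SBML_NS}}}compartment")
    comp.set("id", model.compartment)
    comp.set("spatialDimensions", "3")
    comp.set("size", "1")
    comp.set("constant", "true")

    if model.species:
        los = etree.SubElement(mel, f"{{{SBML_NS}}}listOfSpecies")
        for s in model.species:
            el = etree.SubElement(los, f"{{{SBML_NS}}}species")
            el.set("id", s.id)
            el.set("compartment", model.compartment)
            el.set("initialConcentration", _format_number(s.initial_value))
            el.set("hasOnlySubstanceUnits", "false")
            el.set("boundaryCondition", "false")
            el.set("constant", "false")

    if model.parameters:
        lop = etree.SubElement(mel, f"{{{SBML_NS}}}listOfParameters")
        for p in model.parameters:
            el = etree.SubElement(lop, f"{{{SBML_NS}}}parameter")
            el.set("id", p.id)
            el.set("value", _format_number(p.value))
            el.set("constant", "true")

    if model.reactions:
        lor = etree.SubElement(mel, f"{{{SBML_NS}}}listOfReactions")
        for r in model.reactions:
            rel = etree.SubElement(lor, f"{{{SBML_NS}}}reaction")
            rel.set("id", r.id)
            rel.set("reversible", "false")
            if r.reactants:
                lo = etree.SubElement(rel, f"{{{SBML_NS}}}listOfReactants")
                for ref in r.reactants:
                    sr = etree.SubElement(lo, f"{{{SBML_NS}}}speciesReference")
                    sr.set("species", ref.name)
                    sr.set("stoichiometry", str(ref.stoichiometry))
                    sr.set("constant", "true")
            if r.products:
                lo = etree.SubElement(rel, f"{{{SBML_NS}}}listOfProducts")
                for ref in r.products:
                    sr = etree.SubElement(lo, f"{{{SBML_NS}}}speciesReference")
                    sr.set("species", ref.name)
                    sr.set("stoichiometry", str(ref.stoichiometry))
                    sr.set("constant", "true")
            if r.modifiers:
                lo = etree.SubElement(rel, f"{{{SBML_NS}}}listOfModifiers")
                for name in r.modifiers:
                    sr = etree.SubElement(lo, f"{{{SBML_NS}}}modifierSpeciesReference")
                    sr.set("species", name)
            kl = etree.SubElement(rel, f"{{{SBML_NS}}}kineticLaw")
            math = etree.Element(f"{{{MATHML_NS}}}math", nsmap={None: MATHML_NS})
            math.append(expression_to_mathml(r.rate.expression))
            kl.append(math)

    return etree.tostring(
        root, pretty_print=True, xml_declaration=True, encoding="UTF-8"
    ).decode("utf-8")


# ---------------------------------------------------------------------------
# validator

def _localname(el) -> str:
    try:
        return etree.QName(el).localname
    except ValueError:
        return str(el.tag)


def _iter_named(root, name):
    for el in root.iter():
        if isinstance(el.tag, str) and _localname(el) == name:
            yield el


def validate_sbml(xml: str) -> list[SBMLIssue]:
    """Structural validation; the returned issue list is empty for a valid
    document. Any error-severity issue makes the document invalid."""
    issues: list[SBMLIssue] = []
    if not xml or not xml.strip():
        return [SBMLIssue("error", MALFORMED_XML, "document is empty", "/")]
    try:
        root = etree.fromstring(xml.encode("utf-8"))
    except etree.XMLSyntaxError as exc:
        return [SBMLIssue("error", MALFORMED_XML, str(exc), "/")]

    if _localname(root) != "sbml":
        issues.append(SBMLIssue("error", MALFORMED_XML,
                                f"root element is <{_localname(root)}>, expected <sbml>",
                                "/"))
        return issues

    def check_required(el, path):
        name = _localname(el)
        for attr in REQUIRED_ATTRIBUTES.get(name, ()):
            if el.get(attr) is None:
                issues.append(SBMLIssue(
                    "error", MISSING_REQUIRED_ATTRIBUTE,
                    f"<{name}> lacks required attribute {attr!r}", path))

    check_required(root, "/sbml")
    models = list(_iter_named(root, "model"))
    if not models:
        issues.append(SBMLIssue("error", MALFORMED_XML, "no <model> element", "/sbml"))
        return issues
    model = models[0]

    declared_ids: dict[str, str] = {}

    def register_id(el, path):
        sid = el.get("id")
        if sid is None:
            return
        if not _SID_RE.match(sid):
            issues.append(SBMLIssue("error", INVALID_SID,
                                    f"{sid!r} violates the SId grammar", path))
        elif sid in declared_ids:
            issues.append(SBMLIssue("error", DUPLICATE_ID,
                                    f"id {sid!r} already declared at {declared_ids[sid]}",
                                    path))
        else:
            declared_ids[sid] = path

    species_ids: set[str] = set()
    symbol_ids: set[str] = set()

    for i, el in enumerate(_iter_named(model, "compartment")):
        path = f"/sbml/model/listOfCompartments/compartment[{i}]"
        check_required(el, path)
        register_id(el, path)
        if el.get("id"):
            symbol_ids.add(el.get("id"))

    for i, el in enumerate(_iter_named(model, "species")):
        path = f"/sbml/model/listOfSpecies/species[{i}]"
        check_required(el, path)
        register_id(el, path)
        sid = el.get("id")
        if sid:
            species_ids.add(sid)
            symbol_ids.add(sid)
        if el.get("initialConcentration") is None and el.get("initialAmount") is None:
            issues.append(SBMLIssue(
                "error", NO_INITIAL_STATE,
                f"species {sid or '<anonymous>'} has neither initialConcentration "
                "nor initialAmount", path))

    for i, el in enumerate(_iter_named(model, "parameter")):
        path = f"/sbml/model/listOfParameters/parameter[{i}]"
        check_required(el, path)
        register_id(el, path)
        if el.get("id"):
            symbol_ids.add(el.get("id"))

    for i, rel in enumerate(_iter_named(model, "reaction")):
        rid = rel.get("id") or f"#{i}"
        path = f"/sbml/model/listOfReactions/reaction[{i}]"
        check_required(rel, path)
        register_id(rel, path)
        for tag in ("speciesReference", "modifierSpeciesReference"):
            for el in _iter_named(rel, tag):
                check_required(el, f"{path}/{tag}")
                ref = el.get("species")
                if ref is not None and ref not in species_ids:
                    issues.append(SBMLIssue(
                        "error", UNDECLARED_SPECIES,
                        f"reaction {rid} references undeclared species {ref!r}",
                        f"{path}/{tag}"))
        laws = list(_iter_named(rel, "kineticLaw"))
        if not laws:
            issues.append(SBMLIssue("error", MISSING_KINETIC_LAW,
                                    f"reaction {rid} has no kineticLaw", path))
            continue
        for ci in _iter_named(laws[0], "ci"):
            name = (ci.text or "").strip()
            if name and name not in symbol_ids:
                issues.append(SBMLIssue(
                    "error", UNDECLARED_SPECIES,
                    f"kinetic law of {rid} references undeclared symbol {name!r}",
                    f"{path}/kineticLaw"))

    return issues


# ---------------------------------------------------------------------------
# reader

def read_sbml(xml: str) -> KineticModel:
    """Parse a valid SBML document back into a :class:`KineticModel`.

    The document must pass :func:`validate_sbml` with zero errors.
    """
    errors = [i for i in validate_sbml(xml) if i.severity == "error"]
    if errors:
        raise ValidationError(errors)
    root = etree.fromstring(xml.encode("utf-8"))
    model_el = next(_iter_named(root, "model"))
    model = KineticModel(name=model_el.get("id") or "model")
    comps = list(_iter_named(model_el, "compartment"))
    if comps:
        model.compartment = comps[0].get("id")
    for el in _iter_named(model_el, "species"):
        init = el.get("initialConcentration") or el.get("initialAmount") or "0"
        model.species.append(Species(el.get("id"), float(init)))
    for el in _iter_named(model_el, "parameter"):
        model.parameters.append(Parameter(el.get("id"), float(el.get("value", "1"))))
    for rel in _iter_named(model_el, "reaction"):
        def side(list_name):
            refs = []
            for lo in _iter_named(rel, list_name):
                for el in _iter_named(lo, "speciesReference"):
                    stoich = int(float(el.get("stoichiometry", "1")))
                    refs.append(SpeciesRef(el.get("species"), stoich))
            return refs

        modifiers = [el.get("species") for el in _iter_named(rel, "modifierSpeciesReference")]
        law = next(_iter_named(rel, "kineticLaw"))
        math = next(_iter_named(law, "math"))
        model.reactions.append(Reaction(
            rel.get("id"), side("listOfReactants"), side("listOfProducts"),
            modifiers, RateLaw(mathml_to_expression(math))))
    model.validate()
    return model
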