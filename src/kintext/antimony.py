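"""Emit and parse the Antimony model-definition subset.

The subset covers exactly what generated kinetic models need:

.. code-block:: text

    model decay
      species P;
      J1: P -> ; k1*P;
      k1 = 1;
      P = 1;
    end

* ``species A, B, C;`` declarations (so modifier-only species survive a
  round trip),
* reaction lines ``id: R1 + 2 R2 -> P1; <rate>;`` (empty side allowed),
* ``name = value;`` assignments (parameters first, then initial
  concentrations),
* ``//`` comments.

Rate expressions are serialized with explicit ``*`` and ``^`` and
parenthesized divisions, so they re-parse unambiguously. Emission is
deterministic and byte-stable for equal models.
"""

from __future__ import annotations

import re
import warnings

import sympy as sp
from sympy.parsing.sympy_parser import parse_expr

from .builder import KineticModel, Parameter, RateLaw, Reaction, Species
from .errors import ParseError
from .ir import SpeciesRef

_IDENT_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_]*")


def _format_number(v: float) -> str:
    if float(v).is_integer():
        return str(int(v))
    return repr(float(v))


def format_expression(expr: sp.Expr) -> str:
    """Render a rate expression with explicit ``*``/``^`` operators."""
    text = sp.StrPrinter({"order": "lex"}).doprint(expr)
    return text.replace("**", "^")


def _side_to_text(refs: list[SpeciesRef]) -> str:
    parts = []
    for ref in refs:
        parts.append(ref.name if ref.stoichiometry == 1 else f"{ref.stoichiometry} {ref.name}")
    return " + ".join(parts)


def emit_antimony(model: KineticModel) -> str:
    """Serialize a model as Antimony-subset text (deterministic)."""
    lines = [f"model {model.name}"]
    if model.species:
        lines.append("  // species")
        names = ", ".join(s.id for s in model.species)
        lines.append(f"  species {names};")
    if model.reactions:
        lines.append("  // reactions")
        for r in model.reactions:
            lhs = _side_to_text(r.reactants)
            rhs = _side_to_text(r.products)
            rate = format_expression(r.rate.expression)
            lines.append(f"  {r.id}: {lhs} -> {rhs}; {rate};")
    if model.parameters:
        lines.append("  // parameter values")
        for p in model.parameters:
            lines.append(f"  {p.id} = {_format_number(p.value)};")
    if model.species:
        lines.append("  // initial concentrations")
        for s in model.species:
            lines.append(f"  {s.id} = {_format_number(s.initial_value)};")
    lines.append("end")
    return "\n".join(lines) + "\n"


def parse_rate_expression(text: str, line_no: int | None = None) -> sp.Expr:
    """Parse a serialized rate expression back into a sympy tree.

    Every identifier becomes a plain symbol — names like ``E``, ``S`` or
    ``I`` must not collapse onto sympy's built-in constants.
    """
    cleaned = text.strip().replace("^", "**")
    if not cleaned:
        raise ParseError(f"line {line_no}: empty rate expression")
    local = {name: sp.Symbol(name) for name in set(_IDENT_RE.findall(cleaned))}
    try:
        return parse_expr(cleaned, local_dict=local, evaluate=True)
    except Exception as exc:
        raise ParseError(f"line {line_no}: bad rate expression {text!r}: {exc}") from None


def _parse_side(text: str, line_no: int) -> list[SpeciesRef]:
    text = text.strip()
    if not text:
        return []
    refs = []
    for term in text.split("+"):
        term = term.strip()
        if not term:
            raise ParseError(f"line {line_no}: empty stoichiometric term")
        m = re.fullmatch(r"(?:(\d+)\s+)?([A-Za-z_][A-Za-z0-9_]*)", term)
        if not m:
            raise ParseError(f"line {line_no}: bad stoichiometric term {term!r}")
        stoich = int(m.group(1)) if m.group(1) else 1
        refs.append(SpeciesRef(m.group(2), stoich))
    return refs


_REACTION_RE = re.compile(
    r"(?P<id>[A-Za-z_][A-Za-z0-9_]*)\s*:\s*(?P<lhs>[^;]*?)->(?P<rhs>[^;]*);(?P<rate>[^;]+);?\s*\Z"
)
_ASSIGN_RE = re.compile(
    r"(?P<id>[A-Za-z_][A-Za-z0-9_]*)\s*=\s*(?P<value>[-+0-9.eE]+)\s*;?\s*\Z"
)


def parse_antimony(text: str) -> KineticModel:
    """Parse Antimony-subset text into a :class:`KineticModel`.

    Symbols appearing in rate laws that are neither declared species nor
    assigned values become parameters with default 1.0 (with a warning).
    """
    model = KineticModel()
    declared_species: list[str] = []
    assignments: dict[str, float] = {}
    reactions: list[Reaction] = []
    in_model = False
    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("//", 1)[0].strip()
        if not line:
            continue
        if line.startswith("model"):
            parts = line.split()
            if len(parts) < 2:
                raise ParseError(f"line {line_no}: model line needs a name")
            model.name = parts[1]
            in_model = True
            continue
        if line == "end":
            in_model = False
            continue
        if not in_model:
            raise ParseError(f"line {line_no}: content outside a model block")
        if line.startswith("species "):
            body = line[len("species "):].rstrip(";")
            for name in body.split(","):
                name = name.strip()
                if not _IDENT_RE.fullmatch(name):
                    raise ParseError(f"line {line_no}: bad species name {name!r}")
                if name not in declared_species:
                    declared_species.append(name)
            continue
        m = _REACTION_RE.fullmatch(line)
        if m:
            expr = parse_rate_expression(m.group("rate"), line_no)
            reactions.append(Reaction(
                m.group("id"),
                _parse_side(m.group("lhs"), line_no),
                _parse_side(m.group("rhs"), line_no),
                [],  # modifiers resolved below
                RateLaw(expr),
            ))
            continue
        m = _ASSIGN_RE.fullmatch(line)
        if m:
            assignments[m.group("id")] = float(m.group("value"))
            continue
        raise ParseError(f"line {line_no}: unrecognized Antimony line {raw!r}")

    species_set = set(declared_species)
    for r in reactions:
        for ref in (*r.reactants, *r.products):
            if ref.name not in species_set:
                declared_species.append(ref.name)
                species_set.add(ref.name)

    # classify rate-law symbols: declared species become modifiers when they
    # are absent from the reaction's stoichiometry; everything else is a
    # parameter (defaulting to 1.0 when it carries no assignment).
    parameter_ids: list[str] = []
    seen_params: set[str] = set()
    for r in reactions:
        stoich_names = {ref.name for ref in (*r.reactants, *r.products)}
        for name in sorted(r.rate.symbols()):
            if name in species_set:
                if name not in stoich_names and name not in r.modifiers:
                    r.modifiers.append(name)
            elif name not in seen_params:
                parameter_ids.append(name)
                seen_params.add(name)
                if name not in assignments:
                    warnings.warn(
                        f"symbol {name!r} has no assigned value; "
                        "treating it as a parameter with default 1.0",
                        stacklevel=2,
                    )

    model.species = [
        Species(name, assignments.get(name, 0.0)) for name in declared_species
    ]
    model.parameters = [
        Parameter(name, assignments.get(name, 1.0)) for name in parameter_ids
    ]
    model.reactions = reactions
    model.validate()
    return model
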