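"""Core intermediate representation shared by all pipeline stages.

A natural-language description is translated into a list of
:class:`ReactionStatement` objects — one semantic unit per extracted fact —
which the model builder then turns into a :class:`~kintext.builder.KineticModel`.
This module also houses quantity parsing ("1 uM") and identifier
sanitization (SBML SId grammar, Greek transliteration).
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field

from .errors import ParseError, UnitError

#: The closed set of supported molar concentration units. Values are recorded
#: exactly as written and never converted between units.
MOLAR_UNITS = ("M", "mM", "uM", "nM", "pM")

_SID_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_]*\Z")

# Fixed transliteration table for Greek letters appearing in biochemical
# names (sigma32 and friends). Deterministic: SBML SIds are ASCII-only.
GREEK_TRANSLITERATION = {
    "α": "alpha", "β": "beta", "γ": "gamma", "δ": "delta", "ε": "epsilon",
    "ζ": "zeta", "η": "eta", "θ": "theta", "ι": "iota", "κ": "kappa",
    "λ": "lambda", "μ": "mu", "ν": "nu", "ξ": "xi", "ο": "omicron",
    "π": "pi", "ρ": "rho", "σ": "sigma", "ς": "sigma", "τ": "tau",
    "υ": "upsilon", "φ": "phi", "χ": "chi", "ψ": "psi", "ω": "omega",
    "Α": "Alpha", "Β": "Beta", "Γ": "Gamma", "Δ": "Delta", "Ε": "Epsilon",
    "Ζ": "Zeta", "Η": "Eta", "Θ": "Theta", "Ι": "Iota", "Κ": "Kappa",
    "Λ": "Lambda", "Μ": "Mu", "Ν": "Nu", "Ξ": "Xi", "Ο": "Omicron",
    "Π": "Pi", "Ρ": "Rho", "Σ": "Sigma", "Τ": "Tau", "Υ": "Upsilon",
    "Φ": "Phi", "Χ": "Chi", "Ψ": "Psi", "Ω": "Omega",
}


@dataclass(frozen=True)
class Quantity:
    """A concentration value with its unit, exactly as written in the text."""

    value: float
    unit: str

    def __post_init__(self):
        if self.value < 0:
            raise ParseError(f"concentration must be non-negative, got {self.value}")
        if self.unit not in MOLAR_UNITS:
            raise UnitError(self.unit)

    def __str__(self) -> str:
        v = self.value
        text = str(int(v)) if float(v).is_integer() else repr(v)
        return f"{text} {self.unit}"


@dataclass(frozen=True)
class SpeciesRef:
    """A species name with a stoichiometric coefficient (>= 1)."""

    name: str
    stoichiometry: int = 1

    def __post_init__(self):
        if not self.name:
            raise ParseError("species name must be non-empty")
        if self.stoichiometry < 1:
            raise ParseError(f"stoichiometry must be >= 1, got {self.stoichiometry}")


class StatementKind(enum.Enum):
    """Closed enumeration of semantic statement kinds a rule can map to."""

    DEGRADATION = "degradation"
    SYNTHESIS = "synthesis"
    CONVERSION = "conversion"
    BINDING = "binding"
    DISSOCIATION = "dissociation"
    CATALYSIS = "catalysis"
    EXPRESSION = "expression"
    REGULATION = "regulation"
    INITIAL_CONCENTRATION = "initial_concentration"


#: Regulation signs used in REGULATION statements.
ACTIVATION = "activation"
REPRESSION = "repression"


@dataclass
class ReactionStatement:
    """One semantic unit extracted from a sentence.

    The same type carries all statement kinds; which fields are meaningful
    depends on ``kind`` (e.g. an INITIAL_CONCENTRATION statement has exactly
    one substrate and a quantity, a DEGRADATION statement has no products).
    """

    kind: StatementKind
    substrates: list[SpeciesRef] = field(default_factory=list)
    products: list[SpeciesRef] = field(default_factory=list)
    catalysts: list[str] = field(default_factory=list)
    regulators: list[tuple[str, str]] = field(default_factory=list)
    reversible: bool = False
    quantity: Quantity | None = None
    intermediates: list[str] = field(default_factory=list)
    template: str | None = None  # modifier driving a SYNTHESIS (e.g. its mRNA)
    source_sentence: str = ""

    def __post_init__(self):
        k = StatementKind
        if self.kind is k.INITIAL_CONCENTRATION:
            if len(self.substrates) != 1 or self.products or self.quantity is None:
                raise ParseError(
                    "initial-concentration statement needs exactly one species and a quantity"
                )
        elif self.kind is k.DEGRADATION:
            if not self.substrates or self.products:
                raise ParseError("degradation statement needs >=1 substrate and no products")
        elif self.kind is k.BINDING:
            total = sum(s.stoichiometry for s in self.substrates)
            if total < 2 or len(self.products) != 1:
                raise ParseError(
                    "binding statement needs total substrate stoichiometry >= 2 "
                    "and exactly one product"
                )

    def mentioned_names(self) -> list[str]:
        """All species names referenced, in order of mention (with repeats removed)."""
        names: list[str] = []
        for ref in (*self.substrates, *self.products):
            names.append(ref.name)
        names.extend(self.catalysts)
        names.extend(r for r, _ in self.regulators)
        if self.template:
            names.append(self.template)
        seen: set[str] = set()
        out = []
        for n in names:
            if n not in seen:
                seen.add(n)
                out.append(n)
        return out


_QUANTITY_RE = re.compile(
    r"(?P<num>\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)\s*(?P<unit>\S+)"
)


def parse_quantity(text: str) -> Quantity:
    """Parse a sentence fragment like ``"1 uM"`` into a :class:`Quantity`.

    The unit token must be one of M, mM, uM, nM, pM; no conversion is done.

    >>> parse_quantity("1 uM")
    Quantity(value=1.0, unit='uM')
    """
    m = _QUANTITY_RE.search(text)
    if m is None:
        raise ParseError(f"no numeral found in quantity fragment {text!r}")
    unit = m.group("unit").rstrip(".,;")
    if unit not in MOLAR_UNITS:
        raise UnitError(unit)
    return Quantity(float(m.group("num")), unit)


def sanitize_identifier(name: str) -> str:
    """Map a species/parameter name onto the SBML SId grammar.

    Greek letters transliterate through a fixed table (so "σ32" becomes
    "sigma32"); any other disallowed character becomes an underscore; a
    leading digit gets an underscore prefix. The function is idempotent.
    """
    if not name:
        raise ParseError("identifier must be non-empty")
    out = []
    for ch in name:
        if ch in GREEK_TRANSLITERATION:
            out.append(GREEK_TRANSLITERATION[ch])
        elif ch.isascii() and (ch.isalnum() or ch == "_"):
            out.append(ch)
        else:
            out.append("_")
    result = "".join(out)
    if result[0].isdigit():
        result = "_" + result
    assert _SID_RE.match(result)
    return result


class IdentifierMap:
    """Deterministic, injective name->SId mapping for one model.

    Two distinct raw names that sanitize to the same SId are disambiguated
    with a numeric suffix, in first-come order.
    """

    def __init__(self):
        self._forward: dict[str, str] = {}
        self._taken: set[str] = set()

    def get(self, name: str) -> str:
        if name in self._forward:
            return self._forward[name]
        base = sanitize_identifier(name)
        candidate = base
        n = 2
        while candidate in self._taken:
            candidate = f"{base}_{n}"
            n += 1
        self._forward[name] = candidate
        self._taken.add(candidate)
        return candidate

    def reserve(self, sid: str) -> None:
        """Mark an SId as taken without binding a raw name to it."""
        self._taken.add(sid)
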