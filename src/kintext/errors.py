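"""Exception hierarchy for the kintext pipeline.

Every stage raises a subclass of :class:`KintextError`, so callers (and the
CLI) can distinguish translation, model-building, validation and simulation
failures without string matching.
"""

from __future__ import annotations


class KintextError(Exception):
    """Base class for all kintext errors."""


class ParseError(KintextError):
    """Malformed input text (sentence fragment, Antimony line, identifier)."""


class UnitError(ParseError):
    """A concentration unit outside the supported molar-unit set."""

    def __init__(self, token: str):
        self.token = token
        super().__init__(f"unknown concentration unit {token!r}; expected one of M, mM, uM, nM, pM")


class UnrecognizedSentenceError(KintextError):
    """No conversion rule matched a sentence (strict translation mode)."""

    def __init__(self, sentence: str, index: int | None = None):
        self.sentence = sentence
        self.index = index
        where = f" (sentence {index + 1})" if index is not None else ""
        super().__init__(f"no conversion rule matches{where}: {sentence!r}")


class AmbiguousCatalysisError(KintextError):
    """Enzyme count in a catalysis sentence is neither 1 nor the reaction count."""


class NotSupportedError(KintextError):
    """Construct outside the supported modelling subset (e.g. reversible catalysis)."""


class ConflictError(KintextError):
    """Contradictory statements, e.g. two initial concentrations for one species."""


class ModelError(KintextError):
    """Ill-formed kinetic model (undeclared symbol, missing regulation target...)."""


class ValidationError(KintextError):
    """An SBML document failed structural validation."""

    def __init__(self, issues):
        self.issues = list(issues)
        lines = "; ".join(str(i) for i in self.issues)
        super().__init__(f"invalid SBML document: {lines}")


class SimulationError(KintextError):
    """The ODE integrator failed to produce a trajectory."""


class GenerationError(KintextError):
    """Infeasible size request for the random model generator."""


class VerbalizeError(KintextError):
    """A model contains a reaction the verbalizer has no template for."""
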