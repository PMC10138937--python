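"""Build a kinetic model (species, parameters, reactions, rate laws) from a
statement list.

Rate-law synthesis policy:

* degradation                -> mass action ``k*X``
* synthesis / transcription  -> constant ``v``, multiplied by Hill factors
  (exponent 2, half-saturation ``K = 1``) for each attached regulation
* uncatalyzed conversion, binding, dissociation -> mass action (product of
  reactant concentrations raised to their stoichiometries, one rate constant)
* catalyzed conversion or degradation -> irreversible Michaelis-Menten
  ``kcat*E*S/(Km + S)`` with the enzyme as a modifier
* reversible statements split into forward/backward mass-action reactions
  with independent constants (ids suffixed ``_f`` / ``_r``)

All synthesized parameters default to 1.0: realistic values are a downstream
tuning step, not something a text description can provide. A gene-expression
statement ("E1 is expressed") expands to a four-reaction unit: transcription
of ``mRNA_E1``, translation (mRNA as modifier), mRNA decay and protein decay.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import sympy as sp

from .errors import ConflictError, ModelError, NotSupportedError
from .ir import (
    ACTIVATION,
    IdentifierMap,
    Quantity,
    ReactionStatement,
    SpeciesRef,
    StatementKind,
)

#: Hill exponent used for every regulatory factor.
HILL_EXPONENT = 2


def _sym(name: str) -> sp.Symbol:
    return sp.Symbol(name)


@dataclass(frozen=True)
class Parameter:
    id: str
    value: float = 1.0


@dataclass
class RateLaw:
    """A rate expression tree (sympy) over declared species and parameters."""

    expression: sp.Expr

    def symbols(self) -> set[str]:
        return {s.name for s in self.expression.free_symbols}

    def __eq__(self, other):
        if not isinstance(other, RateLaw):
            return NotImplemented
        if self.expression == other.expression:
            return True
        return sp.simplify(self.expression - other.expression) == 0


@dataclass
class Reaction:
    id: str
    reactants: list[SpeciesRef]
    products: list[SpeciesRef]
    modifiers: list[str]
    rate: RateLaw

    def __post_init__(self):
        if not self.reactants and not self.products:
            raise ModelError(f"reaction {self.id} has neither reactants nor products")


@dataclass
class Species:
    id: str
    initial_value: float = 0.0
    unit: str | None = None


@dataclass
class KineticModel:
    """A complete kinetic model in a single compartment of size 1."""

    name: str = "model"
    compartment: str = "default_compartment"
    species: list[Species] = field(default_factory=list)
    parameters: list[Parameter] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)

    def species_ids(self) -> list[str]:
        return [s.id for s in self.species]

    def parameter_ids(self) -> list[str]:
        return [p.id for p in self.parameters]

    def validate(self) -> None:
        sids = self.species_ids()
        pids = self.parameter_ids()
        if len(set(sids)) != len(sids):
            raise ModelError("duplicate species ids")
        if len(set(pids)) != len(pids):
            raise ModelError("duplicate parameter ids")
        declared = set(sids) | set(pids)
        rids = [r.id for r in self.reactions]
        if len(set(rids)) != len(rids):
            raise ModelError("duplicate reaction ids")
        if set(rids) & set(sids):
            raise ModelError("species and reaction ids overlap")
        for r in self.reactions:
            for ref in (*r.reactants, *r.products):
                if ref.name not in sids:
                    raise ModelError(f"reaction {r.id} references undeclared species {ref.name}")
            for m in r.modifiers:
                if m not in sids:
                    raise ModelError(f"reaction {r.id} modifier {m} is not a declared species")
            missing = r.rate.symbols() - declared
            if missing:
                raise ModelError(f"rate law of {r.id} references undeclared symbols {missing}")


def model_summary(model: KineticModel) -> tuple[int, int, int]:
    """(species count, reaction count, parameter count). Modifiers add nothing."""
    return len(model.species), len(model.reactions), len(model.parameters)


def _hill_factors(regulators, index, target_sid, params):
    """Hill regulation factors multiplying an expression/synthesis rate."""
    factor = sp.Integer(1)
    modifiers = []
    for reg_sid, sign in regulators:
        K = _sym(f"K{index}_{reg_sid}")
        params.append(Parameter(K.name, 1.0))
        R = _sym(reg_sid)
        if sign == ACTIVATION:
            factor *= R**HILL_EXPONENT / (K**HILL_EXPONENT + R**HILL_EXPONENT)
        else:
            factor *= K**HILL_EXPONENT / (K**HILL_EXPONENT + R**HILL_EXPONENT)
        modifiers.append(reg_sid)
    return factor, modifiers


def _mass_action(reactants: list[SpeciesRef], constant: sp.Symbol) -> sp.Expr:
    expr = constant
    for ref in reactants:
        expr *= _sym(ref.name) ** ref.stoichiometry
    return expr


def make_rate_law(
    statement: ReactionStatement,
    index: int,
    sid_of,
    regulators: list[tuple[str, str]] | None = None,
) -> tuple[RateLaw, list[Parameter], list[str]]:
    """Synthesize the rate law for one (single-reaction) statement.

    ``index`` is the reaction counter used for deterministic parameter
    naming; ``sid_of`` maps raw species names to sanitized ids. Returns the
    rate law, the freshly created parameters (all defaulting to 1.0) and the
    modifier species appearing in the law but not in the stoichiometry.
    """
    k = statement.kind
    K = StatementKind
    params: list[Parameter] = []
    if k is K.INITIAL_CONCENTRATION:
        raise ModelError("initial-concentration statements carry no rate law")

    subs = [SpeciesRef(sid_of(r.name), r.stoichiometry) for r in statement.substrates]
    cats = [sid_of(c) for c in statement.catalysts]

    if cats and k in (K.CONVERSION, K.DEGRADATION):
        # irreversible Michaelis-Menten with the enzyme(s) as modifiers
        if statement.reversible:
            raise NotSupportedError("reversible catalysis is not supported")
        if len(subs) != 1:
            raise ModelError("Michaelis-Menten synthesis needs exactly one substrate")
        kcat = _sym(f"kcat{index}")
        Km = _sym(f"Km{index}")
        params += [Parameter(kcat.name), Parameter(Km.name)]
        S = _sym(subs[0].name)
        expr = kcat * sp.Mul(*[_sym(c) for c in cats]) * S / (Km + S)
        return RateLaw(expr), params, cats

    if k is K.DEGRADATION:
        const = _sym(f"k{index}")
        params.append(Parameter(const.name))
        return RateLaw(_mass_action(subs, const)), params, []

    if k in (K.SYNTHESIS, K.EXPRESSION):
        v = _sym(f"v{index}")
        params.append(Parameter(v.name))
        expr = v
        modifiers = []
        if statement.template:
            t_sid = sid_of(statement.template)
            expr *= _sym(t_sid)
            modifiers.append(t_sid)
        factor, reg_mods = _hill_factors(
            [(sid_of(r), s) for r, s in (regulators or [])], index, None, params
        )
        expr *= factor
        modifiers.extend(reg_mods)
        return RateLaw(expr), params, modifiers

    if k in (K.CONVERSION, K.DISSOCIATION) or (k is K.BINDING and not statement.reversible):
        const = _sym(f"k{index}")
        params.append(Parameter(const.name))
        return RateLaw(_mass_action(subs, const)), params, []

    raise ModelError(f"cannot synthesize a single rate law for {k}")


def split_reversible(
    statement: ReactionStatement, index: int, sid_of
) -> tuple[list[Reaction], list[Parameter]]:
    """Split a reversible statement into forward/backward mass-action reactions."""
    if not statement.reversible:
        raise NotSupportedError("split_reversible requires a reversible statement")
    if statement.catalysts:
        raise NotSupportedError("reversible catalysis is not supported")
    subs = [SpeciesRef(sid_of(r.name), r.stoichiometry) for r in statement.substrates]
    prods = [SpeciesRef(sid_of(r.name), r.stoichiometry) for r in statement.products]
    kf = _sym(f"kf{index}")
    kr = _sym(f"kr{index}")
    params = [Parameter(kf.name), Parameter(kr.name)]
    fwd = Reaction(f"J{index}_f", subs, prods, [], RateLaw(_mass_action(subs, kf)))
    bwd = Reaction(f"J{index}_r", prods, subs, [], RateLaw(_mass_action(prods, kr)))
    return [fwd, bwd], params


def build_model(
    statements: list[ReactionStatement],
    name: str = "model",
    default_init: float = 0.0,
) -> KineticModel:
    """Assemble a :class:`KineticModel` from an ordered statement list.

    Species are declared in order of first mention; initial concentrations
    come from INITIAL_CONCENTRATION statements (default ``default_init``
    otherwise); every reaction-bearing statement contributes reactions in
    statement order, forward before backward for reversible steps.
    """
    idmap = IdentifierMap()
    model = KineticModel(name=name)
    declared: dict[str, Species] = {}

    def sid_of(raw: str) -> str:
        sid = idmap.get(raw)
        if sid not in declared:
            s = Species(sid, default_init)
            declared[sid] = s
            model.species.append(s)
        return sid

    # Regulations attach to the expression/synthesis statement of their target.
    regs_by_target: dict[str, list[tuple[str, str]]] = {}
    targets_available: set[str] = set()
    for stmt in statements:
        if stmt.kind is StatementKind.REGULATION:
            regs_by_target.setdefault(stmt.products[0].name, []).extend(stmt.regulators)
        elif stmt.kind in (StatementKind.EXPRESSION, StatementKind.SYNTHESIS):
            targets_available.add(stmt.products[0].name)
    missing = set(regs_by_target) - targets_available
    if missing:
        raise ModelError(
            f"regulation targets without an expression/synthesis statement: {sorted(missing)}"
        )

    seen_init: set[str] = set()
    index = 0
    for stmt in statements:
        kind = stmt.kind
        if kind is StatementKind.INITIAL_CONCENTRATION:
            sid = sid_of(stmt.substrates[0].name)
            if sid in seen_init:
                raise ConflictError(f"duplicate initial concentration for {sid}")
            seen_init.add(sid)
            q: Quantity = stmt.quantity
            declared[sid].initial_value = q.value
            declared[sid].unit = q.unit
            continue
        if kind is StatementKind.REGULATION:
            # modifier only: declare the species, create no reaction
            sid_of(stmt.products[0].name)
            for reg, _ in stmt.regulators:
                sid_of(reg)
            continue
        if kind is StatementKind.CATALYSIS:
            continue  # handled during translation (attach_catalysts)

        if kind is StatementKind.EXPRESSION:
            target_raw = stmt.products[0].name
            protein = sid_of(target_raw)
            mrna = sid_of(f"mRNA_{protein}")
            regs = regs_by_target.get(target_raw, [])
            # transcription (regulated), translation, mRNA decay, protein decay
            index += 1
            rate, params, mods = make_rate_law(
                ReactionStatement(StatementKind.SYNTHESIS, products=[SpeciesRef(mrna)],
                                  source_sentence=stmt.source_sentence),
                index, sid_of, regulators=regs)
            model.parameters += params
            model.reactions.append(Reaction(f"J{index}", [], [SpeciesRef(mrna)], mods, rate))
            index += 1
            ktl = Parameter(f"k{index}")
            model.parameters.append(ktl)
            model.reactions.append(Reaction(
                f"J{index}", [], [SpeciesRef(protein)], [mrna],
                RateLaw(_sym(ktl.id) * _sym(mrna))))
            for decay_target in (mrna, protein):
                index += 1
                kd = Parameter(f"k{index}")
                model.parameters.append(kd)
                model.reactions.append(Reaction(
                    f"J{index}", [SpeciesRef(decay_target)], [], [],
                    RateLaw(_sym(kd.id) * _sym(decay_target))))
            continue

        # declare species in mention order before creating the reaction
        for raw in stmt.mentioned_names():
            sid_of(raw)
        index += 1
        if stmt.reversible:
            reactions, params = split_reversible(stmt, index, sid_of)
            model.reactions += reactions
            model.parameters += params
            continue
        regs = (regs_by_target.get(stmt.products[0].name, [])
                if kind is StatementKind.SYNTHESIS else [])
        rate, params, mods = make_rate_law(stmt, index, sid_of, regulators=regs)
        model.parameters += params
        reactants = [SpeciesRef(sid_of(r.name), r.stoichiometry) for r in stmt.substrates]
        products = [SpeciesRef(sid_of(r.name), r.stoichiometry) for r in stmt.products]
        model.reactions.append(Reaction(f"J{index}", reactants, products, mods, rate))

    model.validate()
    return model


def models_equivalent(a: KineticModel, b: KineticModel) -> bool:
    """Structural equality: species with initial values, parameters with
    values, and reactions (stoichiometry, modifiers, rate expressions modulo
    algebraic identity). Units and model names are not compared."""
    if sorted((s.id, s.initial_value) for s in a.species) != sorted(
        (s.id, s.initial_value) for s in b.species
    ):
        return False
    if sorted((p.id, p.value) for p in a.parameters) != sorted(
        (p.id, p.value) for p in b.parameters
    ):
        return False
    if len(a.reactions) != len(b.reactions):
        return False
    for ra, rb in zip(a.reactions, b.reactions):
        if ra.id != rb.id:
            return False
        if sorted((r.name, r.stoichiometry) for r in ra.reactants) != sorted(
            (r.name, r.stoichiometry) for r in rb.reactants
        ):
            return False
        if sorted((r.name, r.stoichiometry) for r in ra.products) != sorted(
            (r.name, r.stoichiometry) for r in rb.products
        ):
            return False
        if sorted(ra.modifiers) != sorted(rb.modifiers):
            return False
        if ra.rate != rb.rate:
            return False
    return True
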