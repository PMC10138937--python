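"""Random reaction-network generation and natural-language verbalization.

``random_model`` draws a reproducible model of an exact requested size from
five reaction motifs (degradation, conversion, reversible binding, catalyzed
conversion, regulated gene expression). ``verbalize`` renders any model made
of those motifs back into sentences of the default rule table, which makes
the translator round-trip testable without external corpora:
``build_model(translate(verbalize(m))) == m``.
"""

from __future__ import annotations

import random

import sympy as sp

from .builder import KineticModel, Reaction, build_model
from .errors import GenerationError, VerbalizeError
from .ir import Quantity, ReactionStatement, SpeciesRef, StatementKind

_K = StatementKind

# (reaction cost, max new species) per motif
_MOTIFS = {
    "degradation": (1, 1),
    "conversion": (1, 2),
    "binding": (2, 3),       # A + B <=> C
    "binding_dimer": (2, 2),  # 2 A <=> C
    "catalyzed": (1, 3),     # S -> P with enzyme E
    "expression": (4, 2),    # X and mRNA_X, four reactions
}

_INIT_CHOICES = (0.5, 1.0, 2.0, 5.0, 10.0)


# distinct species each motif touches (its reactions are impossible below this)
_MIN_DISTINCT = {
    "degradation": 1,
    "conversion": 2,
    "binding": 3,
    "binding_dimer": 2,
    "catalyzed": 3,
    "expression": 2,
}


def _plan(rng: random.Random, n_reactions: int, n_species: int) -> list[str]:
    plan: list[str] = []
    left = n_reactions
    n_expr = 0
    capacity = 0  # max new species the motifs chosen so far can introduce
    while left > 0:
        # prune motifs that would make n_species unreachable: later reactions
        # introduce at most 3 new species each (catalyzed conversion)
        options = [
            m for m, (cost, cap) in _MOTIFS.items()
            if cost <= left and _MIN_DISTINCT[m] <= n_species
            and (m != "expression" or 2 * (n_expr + 1) <= n_species)
            and capacity + cap + 3 * (left - cost) >= n_species
        ]
        motif = rng.choice(options)
        if motif == "expression":
            n_expr += 1
        plan.append(motif)
        cost, cap = _MOTIFS[motif]
        left -= cost
        capacity += cap
    return plan


def random_model(seed: int, n_species: int, n_reactions: int) -> KineticModel:
    """Generate a reproducible model with exactly the requested size.

    Raises :class:`GenerationError` when no composition of the supported
    motifs can reach the requested (species, reactions) combination.
    """
    if n_species < 1 or n_reactions < 1:
        raise GenerationError("need at least one species and one reaction")
    if n_species > 3 * n_reactions:
        raise GenerationError(
            f"{n_species} species cannot all participate in {n_reactions} reactions"
        )
    rng = random.Random(seed)
    for _attempt in range(500):
        plan = _plan(rng, n_reactions, n_species)
        min_new = sum(2 for m in plan if m == "expression")
        max_new = sum(_MOTIFS[m][1] for m in plan)
        if not (max(min_new, 1) <= n_species <= max_new):
            continue
        statements = _realize(rng, plan, n_species)
        if statements is None:
            continue
        model = build_model(statements, name=f"random_{seed}")
        n_s, n_r, _ = (len(model.species), len(model.reactions), None)
        if (n_s, n_r) != (n_species, n_reactions):  # pragma: no cover - guard
            raise GenerationError(
                f"internal sizing error: got {(n_s, n_r)}, wanted {(n_species, n_reactions)}"
            )
        return model
    raise GenerationError(
        f"no feasible motif composition for {n_species} species / {n_reactions} reactions"
    )


def _realize(rng, plan, n_species):
    pool: list[str] = []          # plain species created so far
    new_left = n_species
    counter = 0
    statements: list[ReactionStatement] = []

    def fresh() -> str:
        nonlocal counter, new_left
        counter += 1
        new_left -= 1
        name = f"X{counter}"
        pool.append(name)
        return name

    def pick_roles(n_roles, min_new, max_new_rest):
        """Choose n distinct species, creating between min_new and the
        budgeted number of fresh ones."""
        nonlocal new_left
        lo = max(min_new, n_roles - len(pool), new_left - max_new_rest)
        hi = min(n_roles, new_left)
        if lo > hi:
            return None
        n_new = rng.randint(lo, hi)
        existing = rng.sample(pool, n_roles - n_new)
        roles = existing + [None] * n_new
        rng.shuffle(roles)
        return [r if r is not None else fresh() for r in roles]

    remaining = list(plan)
    for motif in plan:
        remaining.pop(0)
        rest_capacity = sum(_MOTIFS[m][1] for m in remaining)
        if motif == "expression":
            if new_left < 2:
                return None
            x = fresh()
            new_left -= 1  # the implied mRNA_x also counts toward the budget
            regulator = rng.choice(pool) if pool else x
            sign = rng.choice(("activation", "repression"))
            statements.append(ReactionStatement(_K.EXPRESSION, products=[SpeciesRef(x)]))
            statements.append(ReactionStatement(
                _K.REGULATION, products=[SpeciesRef(x)], regulators=[(regulator, sign)]))
            continue
        if motif == "degradation":
            roles = pick_roles(1, 0, rest_capacity)
            if roles is None:
                return None
            statements.append(ReactionStatement(_K.DEGRADATION,
                                                substrates=[SpeciesRef(roles[0])]))
            continue
        if motif == "conversion":
            roles = pick_roles(2, 0, rest_capacity)
            if roles is None:
                return None
            statements.append(ReactionStatement(
                _K.CONVERSION, substrates=[SpeciesRef(roles[0])],
                products=[SpeciesRef(roles[1])]))
            continue
        if motif == "catalyzed":
            roles = pick_roles(3, 0, rest_capacity)
            if roles is None:
                return None
            statements.append(ReactionStatement(
                _K.CONVERSION, substrates=[SpeciesRef(roles[0])],
                products=[SpeciesRef(roles[1])], catalysts=[roles[2]]))
            continue
        if motif == "binding":
            roles = pick_roles(3, 0, rest_capacity)
            if roles is None:
                return None
            statements.append(ReactionStatement(
                _K.BINDING, substrates=[SpeciesRef(roles[0]), SpeciesRef(roles[1])],
                products=[SpeciesRef(roles[2])], reversible=True))
            continue
        if motif == "binding_dimer":
            roles = pick_roles(2, 0, rest_capacity)
            if roles is None:
                return None
            statements.append(ReactionStatement(
                _K.BINDING, substrates=[SpeciesRef(roles[0], 2)],
                products=[SpeciesRef(roles[1])], reversible=True))
            continue
        raise AssertionError(motif)  # pragma: no cover

    if new_left != 0:
        return None

    # sprinkle initial concentrations over a random subset of species
    for name in list(pool):
        if rng.random() < 0.4:
            value = rng.choice(_INIT_CHOICES)
            statements.append(ReactionStatement(
                _K.INITIAL_CONCENTRATION, substrates=[SpeciesRef(name)],
                quantity=Quantity(value, "uM")))
    return statements


# ---------------------------------------------------------------------------
# verbalization

def _fmt_value(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


def _is_mm(reaction: Reaction) -> bool:
    if len(reaction.reactants) != 1 or not reaction.modifiers:
        return False
    num, den = sp.fraction(sp.together(reaction.rate.expression))
    return den != 1


def _regulation_sentences(reaction: Reaction, protein: str) -> list[str]:
    out = []
    num, _den = sp.fraction(sp.together(reaction.rate.expression))
    num_symbols = {s.name for s in num.free_symbols}
    for reg in reaction.modifiers:
        verb = "activates" if reg in num_symbols else "represses"
        out.append(f"{reg} {verb} the expression of {protein}.")
    return out


def _expression_unit(reactions: list[Reaction], i: int) -> str | None:
    """Return the protein id if reactions[i:i+4] form a gene-expression unit."""
    if i + 3 >= len(reactions):
        return None
    tx, tl, mdeg, pdeg = reactions[i : i + 4]
    if tx.reactants or len(tx.products) != 1:
        return None
    mrna = tx.products[0].name
    if not mrna.startswith("mRNA_"):
        return None
    protein = mrna[len("mRNA_"):]
    if tl.reactants or [p.name for p in tl.products] != [protein] or tl.modifiers != [mrna]:
        return None
    if [r.name for r in mdeg.reactants] != [mrna] or mdeg.products:
        return None
    if [r.name for r in pdeg.reactants] != [protein] or pdeg.products:
        return None
    return protein


def verbalize(model: KineticModel) -> str:
    """Render a model as sentences the default rule table can re-translate.

    Supports the motifs the generator (and the built-in fixtures) emit;
    anything else raises :class:`VerbalizeError`.
    """
    sentences: list[str] = []
    reactions = model.reactions
    i = 0
    while i < len(reactions):
        r = reactions[i]
        # reversible pair J*_f / J*_r
        if (r.id.endswith("_f") and i + 1 < len(reactions)
                and reactions[i + 1].id == r.id[:-2] + "_r"):
            if len(r.products) != 1:
                raise VerbalizeError(f"reversible step {r.id} is not a binding")
            c = r.products[0].name
            if len(r.reactants) == 1 and r.reactants[0].stoichiometry == 2:
                sentences.append(f"Two molecules of {r.reactants[0].name} bind to form {c}.")
            elif len(r.reactants) == 2:
                a, b = (ref.name for ref in r.reactants)
                sentences.append(f"{a} and {b} can bind to form {c}.")
            else:
                raise VerbalizeError(f"unsupported reversible step {r.id}")
            i += 2
            continue
        protein = _expression_unit(reactions, i)
        if protein is not None:
            sentences.append(f"{protein} is expressed.")
            sentences.extend(_regulation_sentences(reactions[i], protein))
            i += 4
            continue
        if not r.reactants and len(r.products) == 1:
            x = r.products[0].name
            if not r.modifiers:
                sentences.append(f"{x} is synthesized.")
            elif len(r.modifiers) == 1 and not _is_mm(r):
                sentences.append(f"{x} is synthesized from {r.modifiers[0]}.")
            else:
                raise VerbalizeError(f"unsupported synthesis form in {r.id}")
            i += 1
            continue
        if len(r.reactants) == 1 and not r.products:
            x = r.reactants[0].name
            if r.modifiers:
                if len(r.modifiers) != 1 or not _is_mm(r):
                    raise VerbalizeError(f"unsupported degradation form in {r.id}")
                sentences.append(f"{x} is degraded by {r.modifiers[0]}.")
            else:
                sentences.append(f"{x} degrades.")
            i += 1
            continue
        if len(r.reactants) == 1 and r.products:
            sub = r.reactants[0].name
            prods = " and ".join(p.name for p in r.products)
            sentences.append(f"{sub} is converted into {prods}.")
            if r.modifiers:
                if not _is_mm(r):
                    raise VerbalizeError(f"unsupported catalysis form in {r.id}")
                enzymes = ", ".join(r.modifiers)
                sentences.append(f"The reaction is catalyzed by the enzyme {enzymes}.")
            i += 1
            continue
        raise VerbalizeError(f"no sentence template for reaction {r.id}")

    for s in model.species:
        if s.initial_value != 0:
            unit = s.unit or "uM"
            sentences.append(
                f"The concentration of {s.id} is {_fmt_value(s.initial_value)} {unit}.")
    return " ".join(sentences)
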