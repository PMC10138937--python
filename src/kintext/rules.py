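"""Deterministic natural-language front end.

Sentences are segmented, split into clauses, and matched against a table of
conversion rules — sentence templates paired with reaction semantics. Each
rule pattern is written in a small template language:

* literal words, matched case-insensitively;
* ``(either|or)`` — alternation between single words;
* ``[optional words]`` — an optional group (may nest slots);
* ``{name:SPECIES}`` — a noun phrase naming one species (role words such as
  "the", "protein", "complex" are tolerated and stripped);
* ``{name:SPECIES_LIST}`` — a comma/"and"-separated list of such phrases;
* ``{name:QUANTITY}`` — a numeral plus a molar unit ("1 uM").

The shipped default table lives in ``data/default_rules.tsv`` (one rule per
line: PATTERN, KIND, SLOT_MAP, tab-separated, ``#`` comments). Matching does
not require an exact literal match between rule and sentence: the species
slots absorb articles and role nouns, so "Protein P decays" satisfies the
rule "X degrades (or decays)".
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from importlib import resources

from .errors import (
    AmbiguousCatalysisError,
    ParseError,
    UnrecognizedSentenceError,
)
from .ir import (
    ReactionStatement,
    SpeciesRef,
    StatementKind,
    parse_quantity,
)

# ---------------------------------------------------------------------------
# sentence segmentation

#: Abbreviations that must never terminate a sentence, even though they end
#: with a period. Configurable per call to split_sentences.
DEFAULT_ABBREVIATIONS = ("E. coli", "S. cerevisiae", "i.e.", "e.g.", "et al.", "vs.")

# A sentence boundary is '.' or ';' followed by whitespace and a capital
# letter, a Greek letter (species such as σ32 may open a sentence), or a digit.
_BOUNDARY_RE = re.compile(r"(?<=[.;])\s+(?=[A-Z0-9Ͱ-Ͽ])")


def split_sentences(text: str, abbreviations: tuple[str, ...] = DEFAULT_ABBREVIATIONS) -> list[str]:
    """Split a description into sentences.

    The concatenation of the returned sentences equals the input up to
    delimiters and surrounding whitespace; abbreviations in the guard list
    are never split.
    """
    if not text or not text.strip():
        return []
    protected = text
    sentinel_map = {}
    for i, abbr in enumerate(abbreviations):
        token = f"\x00{i}\x00"
        sentinel_map[token] = abbr
        protected = protected.replace(abbr, token)
    pieces = _BOUNDARY_RE.split(protected.strip())
    out = []
    for piece in pieces:
        for token, abbr in sentinel_map.items():
            piece = piece.replace(token, abbr)
        piece = piece.strip()
        if piece and piece[-1] in ".;":
            piece = piece[:-1].rstrip()
        if piece:
            out.append(piece)
    return out


# ---------------------------------------------------------------------------
# clause segmentation within one sentence

_CLAUSE_SEP_RE = re.compile(r"(,\s+and\s+|,\s+|\s+and\s+)")
_VERB_RE = re.compile(
    r"\b(?:is|are|degrades?|decays?|binds?|bind|dissociates?|activates?|"
    r"represses?|forms?)\b",
    re.IGNORECASE,
)


def _starts_new_clause(fragment: str) -> bool:
    """A fragment opens a clause when a verb occurs after a subject word."""
    words = fragment.split()
    if words and words[0].lower() in ("and", "then"):
        words = words[1:]
    for i, w in enumerate(words):
        if _VERB_RE.fullmatch(w.strip(".,;")):
            return i >= 1
    return False


def split_clauses(sentence: str) -> list[str]:
    """Split a sentence into coordinated clauses, keeping lists intact.

    Fragments without a subject+verb of their own ("E2", "and E3", "the
    product P") are rejoined to the clause under construction, so
    enumerations like "three enzymes, E1, E2, and E3" survive.
    """
    parts = _CLAUSE_SEP_RE.split(sentence)
    clauses: list[str] = []
    current = ""
    current_has_verb = False
    pending_sep = ""
    for i, part in enumerate(parts):
        if i % 2 == 1:  # separator
            pending_sep = part
            continue
        if not part:
            continue
        if current and current_has_verb and _starts_new_clause(part):
            clauses.append(current)
            current = part
            current_has_verb = True
        else:
            current = current + pending_sep + part if current else part
            current_has_verb = current_has_verb or bool(_VERB_RE.search(part))
        pending_sep = ""
    if current:
        clauses.append(current)
    return clauses


# ---------------------------------------------------------------------------
# noun-phrase cleanup

#: Common role/filler words tolerated before species names and dropped during
#: slot cleanup. Species identifiers ("DnaK", "mRNA_sigma32") never collide
#: with these whole-word, case-insensitive entries.
DEFAULT_ROLE_WORDS = frozenset(
    """
    the a an of two three four protein proteins substrate substrates product
    products enzyme enzymes complex complexes molecule molecules monomer
    monomers inhibitor inhibitors chaperone chaperones protease proteases
    metabolite metabolites intermediate intermediates mrna mrnas gene genes
    factor factors polymerase holoenzyme sigma active irreversible reversible
    nascent folded unfolded accumulated free total metabolic initial
    """.split()
)


class _NoMatch(Exception):
    """Internal: slot cleanup failed, try the next rule."""


def _is_role_word(token: str, role_words: frozenset[str]) -> bool:
    # single uppercase letters are species names ("A", "P"), never articles
    if len(token) == 1 and token.isupper():
        return False
    return token.lower() in role_words


def _clean_species(phrase: str, role_words: frozenset[str]) -> str:
    tokens = [t.strip("()“”\"'") for t in phrase.split()]
    kept = [t for t in tokens if t and not _is_role_word(t, role_words)]
    if len(kept) != 1:
        raise _NoMatch(phrase)
    return kept[0]


_LIST_SPLIT_RE = re.compile(r",\s*(?:and\s+)?|\s+and\s+", re.IGNORECASE)


def _clean_species_list(phrase: str, role_words: frozenset[str]) -> list[str]:
    names = []
    for item in _LIST_SPLIT_RE.split(phrase):
        item = item.strip()
        if not item:
            continue
        tokens = [t.strip("()“”\"'") for t in item.split()]
        kept = [t for t in tokens if t and not _is_role_word(t, role_words)]
        if len(kept) > 1:
            raise _NoMatch(item)
        if kept:
            names.append(kept[0])
    if not names:
        raise _NoMatch(phrase)
    return names


# ---------------------------------------------------------------------------
# rule templates

_SLOT_REGEX = {
    "SPECIES": r"[^,.;]+?",
    "SPECIES_LIST": r"[^.;]+?",
    "QUANTITY": r"\d[\d.eE+-]*\s*\S+",
}


class _Node:
    optional = False


class _Word(_Node):
    def __init__(self, text: str):
        self.text = text

    def render(self) -> str:
        return re.escape(self.text)


class _Alt(_Node):
    def __init__(self, options: list[str]):
        self.options = options

    def render(self) -> str:
        return "(?:" + "|".join(re.escape(o) for o in self.options) + ")"


class _Slot(_Node):
    def __init__(self, name: str, type_: str):
        if type_ not in _SLOT_REGEX:
            raise ParseError(f"unknown slot type {type_!r}")
        self.name = name
        self.type_ = type_

    def render(self) -> str:
        return f"(?P<{self.name}>{_SLOT_REGEX[self.type_]})"


class _Opt(_Node):
    optional = True

    def __init__(self, seq: list[_Node]):
        self.seq = seq

    def render(self) -> str:
        return _render_seq(self.seq)


def _render_seq(seq: list[_Node]) -> str:
    out = ""
    seen_mandatory = False
    for node in seq:
        r = node.render()
        if node.optional:
            out += f"(?:\\s+{r})?" if seen_mandatory else f"(?:{r}\\s+)?"
        else:
            out += f"\\s+{r}" if seen_mandatory else r
            seen_mandatory = True
    return out


def _parse_template(text: str) -> list[_Node]:
    nodes, i = _parse_seq(text, 0, stop=None)
    return nodes


def _parse_seq(text: str, i: int, stop: str | None) -> tuple[list[_Node], int]:
    nodes: list[_Node] = []
    while i < len(text):
        ch = text[i]
        if stop and ch == stop:
            return nodes, i + 1
        if ch.isspace():
            i += 1
        elif ch == "[":
            inner, i = _parse_seq(text, i + 1, stop="]")
            nodes.append(_Opt(inner))
        elif ch == "(":
            j = text.index(")", i)
            nodes.append(_Alt(text[i + 1 : j].split("|")))
            i = j + 1
        elif ch == "{":
            j = text.index("}", i)
            name, type_ = text[i + 1 : j].split(":")
            nodes.append(_Slot(name.strip(), type_.strip()))
            i = j + 1
        else:
            j = i
            while j < len(text) and not text[j].isspace() and text[j] not in "[]({":
                j += 1
            nodes.append(_Word(text[i:j]))
            i = j
    if stop:
        raise ParseError(f"unterminated {stop!r} group in template {text!r}")
    return nodes, i


@dataclass
class ConversionRule:
    """One natural-language pattern template mapped to a statement kind."""

    pattern: str
    kind: StatementKind
    slot_map: dict[str, str]
    consts: dict[str, str]
    priority: int
    regex: re.Pattern = field(init=False, repr=False)

    def __post_init__(self):
        body = _render_seq(_parse_template(self.pattern))
        self.regex = re.compile(body, re.IGNORECASE)
        slots = {n.name for n in _flatten(_parse_template(self.pattern)) if isinstance(n, _Slot)}
        mapped = set(self.slot_map)
        if slots != mapped:
            raise ParseError(
                f"slot map {sorted(mapped)} does not cover pattern slots {sorted(slots)} "
                f"in rule {self.pattern!r}"
            )


def _flatten(seq: list[_Node]):
    for node in seq:
        if isinstance(node, _Opt):
            yield from _flatten(node.seq)
        else:
            yield node


def _parse_slot_map(text: str) -> tuple[dict[str, str], dict[str, str]]:
    slot_map: dict[str, str] = {}
    consts: dict[str, str] = {}
    text = text.strip()
    if text in ("", "-"):
        return slot_map, consts
    for token in text.split(","):
        token = token.strip()
        if "=" in token:
            k, v = token.split("=", 1)
            slot_map[k.strip()] = v.strip()
        elif ":" in token:
            k, v = token.split(":", 1)
            consts[k.strip()] = v.strip()
        else:
            raise ParseError(f"bad slot-map token {token!r}")
    return slot_map, consts


class RuleTable:
    """Ordered list of conversion rules; earlier rows have higher priority."""

    def __init__(self, rules: list[ConversionRule]):
        seen = set()
        for r in rules:
            key = (r.pattern, r.kind)
            if key in seen:
                raise ParseError(f"duplicate rule (pattern, kind): {key}")
            seen.add(key)
        self.rules = list(rules)

    @classmethod
    def from_text(cls, text: str) -> "RuleTable":
        rules = []
        for lineno, line in enumerate(text.splitlines(), start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ParseError(f"rule table line {lineno}: expected 3 tab-separated columns")
            pattern, kind_name, slot_text = cols[0].strip(), cols[1].strip(), cols[2].strip()
            try:
                kind = StatementKind[kind_name]
            except KeyError:
                raise ParseError(f"rule table line {lineno}: unknown kind {kind_name!r}") from None
            slot_map, consts = _parse_slot_map(slot_text)
            rules.append(ConversionRule(pattern, kind, slot_map, consts, priority=len(rules)))
        return cls(rules)

    @classmethod
    def load(cls, path) -> "RuleTable":
        with open(path, encoding="utf-8") as fh:
            return cls.from_text(fh.read())

    @classmethod
    def default(cls) -> "RuleTable":
        text = resources.files("kintext").joinpath("data/default_rules.tsv").read_text("utf-8")
        return cls.from_text(text)


# ---------------------------------------------------------------------------
# matching and assembly

def _assemble(
    rule: ConversionRule,
    match: re.Match,
    context: str | None,
    sentence: str,
    role_words: frozenset[str],
) -> list[ReactionStatement]:
    g = match.groupdict()

    def slot(field_name: str) -> str | None:
        for slot_name, mapped in rule.slot_map.items():
            if mapped == field_name:
                return g.get(slot_name)
        return None

    k = rule.kind
    K = StatementKind
    if k is K.INITIAL_CONCENTRATION:
        raw = slot("substrate")
        if raw is not None:
            name = _clean_species(raw, role_words)
        elif context is not None:
            name = context
        else:
            raise ParseError(
                f"quantity sentence has no species and no antecedent: {sentence!r}"
            )
        q = parse_quantity(slot("quantity"))
        return [ReactionStatement(k, substrates=[SpeciesRef(name)], quantity=q,
                                  source_sentence=sentence)]
    if k is K.DEGRADATION:
        names = _clean_species_list(slot("substrates"), role_words)
        cat_raw = slot("catalyst")
        cats = [_clean_species(cat_raw, role_words)] if cat_raw else []
        return [
            ReactionStatement(k, substrates=[SpeciesRef(n)], catalysts=list(cats),
                              source_sentence=sentence)
            for n in names
        ]
    if k is K.CONVERSION:
        sub = _clean_species(slot("substrate"), role_words)
        prods = _clean_species_list(slot("products"), role_words)
        inter_raw = slot("intermediates")
        inters = _clean_species_list(inter_raw, role_words) if inter_raw else []
        return [ReactionStatement(
            k, substrates=[SpeciesRef(sub)], products=[SpeciesRef(p) for p in prods],
            intermediates=inters, source_sentence=sentence)]
    if k is K.BINDING:
        reversible = rule.consts.get("reversible", "true") == "true"
        z = _clean_species(slot("product"), role_words)
        x = _clean_species(slot("substrate"), role_words)
        if rule.consts.get("stoich") == "2":
            subs = [SpeciesRef(x, 2)]
        else:
            y = _clean_species(slot("substrate2"), role_words)
            subs = [SpeciesRef(x), SpeciesRef(y)]
        return [ReactionStatement(k, substrates=subs, products=[SpeciesRef(z)],
                                  reversible=reversible, source_sentence=sentence)]
    if k is K.DISSOCIATION:
        x = _clean_species(slot("substrate"), role_words)
        y = _clean_species(slot("product"), role_words)
        z = _clean_species(slot("product2"), role_words)
        return [ReactionStatement(k, substrates=[SpeciesRef(x)],
                                  products=[SpeciesRef(y), SpeciesRef(z)],
                                  source_sentence=sentence)]
    if k is K.CATALYSIS:
        cats = _clean_species_list(slot("catalysts"), role_words)
        return [ReactionStatement(k, catalysts=cats, source_sentence=sentence)]
    if k is K.EXPRESSION:
        targets = _clean_species_list(slot("targets"), role_words)
        return [ReactionStatement(k, products=[SpeciesRef(t)], source_sentence=sentence)
                for t in targets]
    if k is K.SYNTHESIS:
        targets = _clean_species_list(slot("targets"), role_words)
        t_raw = slot("template")
        template = _clean_species(t_raw, role_words) if t_raw else None
        return [ReactionStatement(k, products=[SpeciesRef(t)], template=template,
                                  source_sentence=sentence)
                for t in targets]
    if k is K.REGULATION:
        reg = _clean_species(slot("regulator"), role_words)
        sign = rule.consts["sign"]
        targets = _clean_species_list(slot("targets"), role_words)
        return [ReactionStatement(k, products=[SpeciesRef(t)], regulators=[(reg, sign)],
                                  source_sentence=sentence)
                for t in targets]
    raise ParseError(f"unhandled statement kind {k}")  # pragma: no cover


def match_sentence(
    sentence: str,
    table: RuleTable | None = None,
    context: str | None = None,
    role_words: frozenset[str] = DEFAULT_ROLE_WORDS,
) -> list[ReactionStatement]:
    """Extract all reaction statements from one sentence.

    The sentence is split into coordinated clauses and each clause is matched
    against the rule table in priority order (first full match wins). A
    quantity clause without an explicit species attaches to ``context``, the
    most recently mentioned species.
    """
    if not sentence.strip():
        raise UnrecognizedSentenceError(sentence)
    table = table or RuleTable.default()
    statements: list[ReactionStatement] = []
    for clause in split_clauses(sentence):
        matched = False
        for rule in table.rules:
            m = rule.regex.fullmatch(clause.strip())
            if m is None:
                continue
            try:
                stmts = _assemble(rule, m, context, sentence, role_words)
            except _NoMatch:
                continue
            statements.extend(stmts)
            for s in stmts:
                names = s.mentioned_names()
                if names:
                    context = names[-1]
            matched = True
            break
        if not matched:
            raise UnrecognizedSentenceError(sentence)
    return statements


def expand_pathway(statement: ReactionStatement) -> list[ReactionStatement]:
    """Expand a CONVERSION through n intermediates into n+1 chained steps."""
    if statement.kind is not StatementKind.CONVERSION or not statement.intermediates:
        return [statement]
    if len(set(statement.intermediates)) != len(statement.intermediates):
        raise ParseError(f"duplicate intermediate names in {statement.intermediates}")
    if len(statement.products) != 1:
        raise ParseError("a pathway through intermediates must have a single end product")
    chain = [statement.substrates[0].name, *statement.intermediates,
             statement.products[0].name]
    if len(set(chain)) != len(chain):
        raise ParseError(f"pathway endpoints repeat an intermediate: {chain}")
    return [
        ReactionStatement(
            StatementKind.CONVERSION,
            substrates=[SpeciesRef(a)], products=[SpeciesRef(b)],
            source_sentence=statement.source_sentence,
        )
        for a, b in zip(chain, chain[1:])
    ]


def attach_catalysts(
    statements: list[ReactionStatement], catalysis: ReactionStatement
) -> list[ReactionStatement]:
    """Assign the enzymes of a CATALYSIS statement to uncatalyzed conversions.

    With k enzymes and m conversions: k == m assigns pairwise in order of
    mention; k == 1 assigns the single enzyme to every step; anything else is
    ambiguous.
    """
    k = len(catalysis.catalysts)
    m = len(statements)
    if m == 0:
        raise AmbiguousCatalysisError(
            f"no uncatalyzed reaction precedes: {catalysis.source_sentence!r}"
        )
    if k == m:
        for stmt, enzyme in zip(statements, catalysis.catalysts):
            stmt.catalysts = [enzyme]
    elif k == 1:
        for stmt in statements:
            stmt.catalysts = list(catalysis.catalysts)
    else:
        raise AmbiguousCatalysisError(
            f"{k} enzymes cannot be assigned to {m} reactions: "
            f"{catalysis.source_sentence!r}"
        )
    return statements


def translate(
    text: str,
    table: RuleTable | None = None,
    strict: bool = True,
    abbreviations: tuple[str, ...] = DEFAULT_ABBREVIATIONS,
    role_words: frozenset[str] = DEFAULT_ROLE_WORDS,
) -> list[ReactionStatement]:
    """Translate a full description into an ordered statement list.

    Composition of sentence splitting, rule matching, pathway expansion and
    catalyst attachment. A catalysis sentence binds to the uncatalyzed
    CONVERSION statements of the same or the immediately preceding sentence.
    In lenient mode unmatched sentences are warnings rather than errors.
    """
    table = table or RuleTable.default()
    result: list[ReactionStatement] = []
    context: str | None = None
    prev_group: list[ReactionStatement] = []
    for idx, sentence in enumerate(split_sentences(text, abbreviations)):
        try:
            raw = match_sentence(sentence, table, context, role_words)
        except UnrecognizedSentenceError as exc:
            if strict:
                raise UnrecognizedSentenceError(sentence, idx) from None
            warnings.warn(f"skipping unrecognized sentence {idx + 1}: {sentence!r}",
                          stacklevel=2)
            continue
        group: list[ReactionStatement] = []
        for stmt in raw:
            if stmt.kind is StatementKind.CATALYSIS:
                pool = [s for s in group
                        if s.kind is StatementKind.CONVERSION and not s.catalysts]
                if not pool:
                    pool = [s for s in prev_group
                            if s.kind is StatementKind.CONVERSION and not s.catalysts]
                attach_catalysts(pool, stmt)
            else:
                group.extend(expand_pathway(stmt))
            names = stmt.mentioned_names()
            if names:
                context = names[-1]
        result.extend(group)
        if group:
            prev_group = group
    return result
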