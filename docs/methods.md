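# Methods

## Problem and approach

Kinetic models in systems biology are ODE systems over molecular
concentrations, exchanged as SBML. Writing them is expert work, and
generating SBML free-form from text is brittle: one missing required
attribute invalidates a document. kintext therefore compiles natural
language through two constrained hops — text to a typed statement list, and
statements to a kinetic model — and only then serializes to Antimony or
SBML. Every stage is deterministic, so identical input text always yields
byte-identical output.

## The conversion-rule front end

A rule is a sentence template plus reaction semantics. Templates use literal
words (case-insensitive), alternations `(degrades|decays)`, optional groups
`[the]`, and three slot types: `SPECIES` (one noun phrase), `SPECIES_LIST`
(comma/"and" enumeration), `QUANTITY` (numeral + molar unit from the closed
set M, mM, uM, nM, pM; values are recorded as written and never
unit-converted). The shipped table (`src/kintext/data/default_rules.tsv`,
TSV: pattern, kind, slot map; `#` comments) covers degradation (plain and
protease-mediated), conversion with optional intermediates, binding
(pairwise and dimerization), dissociation, catalysis, expression, synthesis
(optionally templated "from" a driver species), Hill regulation, and initial
concentrations. Priority is table order; within a clause the first full
match wins.

Design choices that needed a decision:

- **Approximate matching.** Slots absorb *role words* (articles and common
  nouns: "the enzyme E", "an active enzyme E", "the chaperones DnaK and
  GroEL"). A single uppercase letter is always a species name, never the
  article "a". The role-word lexicon is a parameter of the matcher.
- **Sentence segmentation** splits at `.`/`;` followed by whitespace and an
  uppercase Latin letter, a Greek letter (σ32 may open a sentence), or a
  digit. A configurable abbreviation guard ("E. coli", "i.e.", …) is
  protected before splitting. Concatenating the output reproduces the input
  up to delimiters and whitespace.
- **Clause segmentation.** Sentences are split at commas/" and " into
  fragments; a fragment opens a new clause only when it carries its own
  subject + verb, so enumerations ("three enzymes, E1, E2, and E3") stay
  inside one clause while genuine coordination ("…, and the enzyme E can
  bind…") is matched clause by clause. One sentence can thus yield several
  statements.
- **Anaphora** is deliberately minimal: a quantity sentence without an
  explicit species attaches to the most recently mentioned species. Nothing
  else is resolved across sentences.
- **Catalysis attachment.** "The metabolic reactions are catalyzed by three
  enzymes, E1, E2, and E3" attaches to the uncatalyzed conversion statements
  of the same or the immediately preceding sentence: k enzymes onto m steps
  pairwise when k = m, broadcast when k = 1, ambiguous otherwise. The
  sentence-scoped window keeps attachment deterministic for both dense
  pathway sentences and one-sentence-per-reaction text.
- **Reversibility default.** Complex-formation ("can bind … to form") is
  reversible; "is converted into" is irreversible. This convention is what
  makes the HIV mechanism count 10 reactions over 9 species.
- Strict mode fails on any unmatched sentence (exit code 2 in the CLI);
  lenient mode downgrades to a warning and drops the sentence.

## Rate-law synthesis

Per statement kind (all generated parameters default to 1.0, since the text
carries no kinetics; parameter names derive from the reaction counter, so
generation is reproducible):

| statement | rate law |
|---|---|
| degradation | `k·X` |
| synthesis / transcription | `v` (· template driver) (· Hill factors) |
| conversion / dissociation / irreversible binding | mass action, `k·∏[Xᵢ]^νᵢ` |
| catalyzed conversion or degradation | `kcat·E·S/(Km+S)` (enzyme = modifier) |
| reversible statement | forward + backward mass action, `kf`/`kr`, ids `J*_f`/`J*_r` |

Regulation never creates a reaction: it multiplies the target's
transcription (or synthesis) rate by a Hill factor with exponent 2 and
half-saturation K = 1 — activation `A²/(K²+A²)`, repression `K²/(K²+R²)` —
and adds the regulator as a modifier. A gene-expression statement expands to
a four-reaction unit: transcription of `mRNA_X` (carrying any Hill factors),
translation (`mRNA_X` as modifier), mRNA decay, protein decay. Catalyzed
degradation ("σ32 is degraded by FtsH") uses the same Michaelis–Menten form
with an empty product side — proteolysis saturates like any enzyme reaction.

Models live in a single compartment of size 1. Species default to initial
concentration 0 unless the text states one (`--default-init` overrides).
Identifiers are sanitized to the SBML SId grammar with a fixed Greek
transliteration table (σ32 → sigma32); collisions get numeric suffixes, so
the mapping is injective per model.

## Serialization

**Antimony subset.** `model … end`, a `species A, B, C;` declaration,
reaction lines `id: R1 + 2 R2 -> P1; rate;`, assignments `name = value;`,
`//` comments. Rates print with explicit `*`/`^` and parenthesized division
so they re-parse unambiguously. The species declaration is part of the
grammar because a catalyst that appears only in a rate law would otherwise
be indistinguishable from a parameter when parsing; with it, the emit/parse
pair is a structural identity on every model the builder can produce.
Symbols in rate expressions that are neither declared species nor assigned
values parse as parameters with default 1.0 plus a warning.

**SBML.** Level 3 Version 2 Core, written with lxml: one constant
compartment, fully attributed species (`initialConcentration`,
`hasOnlySubstanceUnits`, `boundaryCondition`, `constant`), global parameters
(global rather than reaction-local: simpler round trip, observationally
identical dynamics), reactions with reactant/product/modifier lists and
content-MathML kinetic laws (`plus/times/divide/power` plus `minus` on
read). The validator implements a fixed structural subset of the SBML
consistency rules — well-formed XML, required attributes per element, SId
grammar, id uniqueness, declared references in stoichiometry and MathML,
defined initial state, kinetic-law presence — and returns typed issues;
one error-severity issue makes a document invalid. It is intentionally
self-contained and offline, not a proxy for a full rule-catalogue validator;
events, function definitions, and unit validation are out of scope.

## Simulation

`d[X]/dt = N·v(X)` with N the species × reactions stoichiometric matrix
(modifiers contribute zero). Rate laws are compiled once via sympy lambdify;
integration is LSODA (stiff-capable — the heat-shock model mixes fast
binding with slow expression) on a uniform output grid. Default tolerances
rtol 1e-8 / atol 1e-10: at these settings simple decay tracks its closed
form and stoichiometric conservation sums stay constant to well below 1e-6
over the horizons used here. Observables are expressions over species
evaluated along the trajectory; trajectories export to CSV
(`time` + species + observables). Parameter and initial-value overrides are
applied at simulation time — a step perturbation active from t = 0, such as
a heat shock applied as an elevated denaturation rate constant, is an
override rather than an SBML event (events are out of scope).

## The built-in problems

- **decay** — the canonical two-sentence description; 1 species, 1 reaction.
- **hiv** — irreversible inhibition of HIV proteinase in five sentences:
  2M ⇌ E, E+S ⇌ ES, ES → E+P, E+P ⇌ EP, E+I ⇌ EI, EI → EJ. This is the
  minimal mechanism consistent with the narrated biology, and with
  reversible steps counted twice it gives exactly 9 species / 10 reactions.
  Its stoichiometry has a 3-dimensional left null space; the test suite
  checks the two named pools (S+ES+P+EP and E+ES+EP+EI+EJ+M/2) against a
  null-space oracle and along trajectories.
- **three_step** — S → M1 → M2 → P with Michaelis–Menten enzymes E1–E3,
  a four-reaction expression unit per enzyme, and three gene regulations
  (S induces E1 and E2; accumulated P represses E3). The unit decomposition
  (3 metabolic + 3×4 expression = 15 reactions; 4 metabolites + 3 mRNAs +
  3 enzymes = 10 species) is the only one consistent with those totals.
  The named regulation is P ⊣ E3; the two inductions are a fixture choice.
- **heat_shock** — a synthetic 20-sentence description of the *E. coli*
  σ32 circuit (flagged `synthetic` in `fixtures/manifest.json`): heat
  activates σ32 mRNA synthesis; σ32 drives expression of DnaK, GroEL, FtsH
  and HslVU; DnaK sequesters σ32; FtsH degrades free and DnaK-bound σ32;
  DnaK and GroEL refold denatured protein (Punfold ⇌ complexes → Pfold);
  proteases capture unfolded protein; σ70/RNAP holoenzyme competition; slow
  synthesis of new protein. Sized to exactly 25 species / 50 reactions.

Demonstration parameter sets (in `problems.py`, all other parameters at the
generated default 1.0) reproduce the qualitative dynamics: HIV substrate →
product conversion with monotone EJ accumulation, three-step E3 repression,
and the heat-shock yield `Pfold/(Pfold+Punfold+Punfold_DnaK)` dipping to
≈0.44 two minutes after the shock and recovering above 0.9 of its initial
value as chaperones accumulate. These sets are illustrative, not fitted to
any experimental data; quantitative reproduction of published simulation
figures is out of scope because their tuned parameter values are not
published.

## Random models and the round-trip property

`random_model(seed, n_species, n_reactions)` draws a plan of motifs
(degradation, conversion, reversible binding incl. dimerization, catalyzed
conversion, regulated expression) whose reaction costs sum exactly to the
request, pruning motifs that would make the species count unreachable
(each reaction introduces at most 3 new species), then assigns roles so the
species count lands exactly; every species participates in at least one
reaction, initial concentrations are sprinkled over a random subset, and
everything is reproducible per seed. `verbalize` renders a model back into
rule-table sentences by recognizing the motifs in the reaction list
(reversible `_f`/`_r` pairs, four-reaction expression units with regulation
signs recovered from the Hill numerator, Michaelis–Menten forms). The
round-trip property — translate + build on the verbalized text reproduces
the model structurally (species with initial values, parameters,
stoichiometry, modifiers, rate expression trees) — is checked over 100
seeded models in the acceptance tests. The generator emits a single unit
(uM) throughout; mixed-unit descriptions are recorded but never converted,
and dimensional analysis is a non-goal.

## Known limitations

- The front end is template matching, not NLP: passives, relative clauses,
  or coreference beyond the quantity-sentence rule are unsupported; unknown
  sentences fail loudly (strict) or are skipped with a warning (lenient).
- Reversible Michaelis–Menten, SBML events/rules/function definitions,
  stochastic simulation, steady-state analysis, and parameter estimation are
  out of scope.
- The verbalizer covers the generator's motif set; hand-built models outside
  it raise `VerbalizeError`.
- Antimony coverage is the subset above, not the full language; arbitrary
  external SBML is readable only insofar as it uses the same constructs.
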