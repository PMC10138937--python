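# kintext

**kintext** compiles plain-English descriptions of biochemical reaction
systems into executable kinetic models. A description like

> Protein P decays. The initial concentration is 1 uM.

becomes an [Antimony](https://tellurium.readthedocs.io/en/latest/antimony.html)
model, a valid SBML Level 3 Version 2 document, and an ODE system that can be
simulated directly. The translation front end is fully deterministic: a
table of *conversion rules* — sentence templates such as
"X degrades (or decays)" or "X (concentration) is Y M (or mM, uM, nM, pM)" —
is matched against each sentence, tolerating articles and role nouns
("the enzyme E", "an active enzyme E") rather than requiring exact wording.
The rule table is a plain TSV file users can extend; the translator is also
an interface behind which other back ends (e.g. an LLM) could be plugged.

It is a library first (`import kintext`), with a thin `kintext` CLI for
shell pipelines and an `examples/` directory of narrative scripts.

## Who this is for

Systems biologists who want to go from a mechanistic paragraph — a metabolic
pathway, a protein-interaction network, a stress-response circuit — to a
simulatable, standards-compliant SBML model without hand-writing XML or rate
equations. Writing SBML by hand (or having a language model write it
free-form) reliably fails structural validation on details like missing
required attributes; compiling through a constrained intermediate
representation cannot.

## What it computes

The pipeline is `text → statements → model → Antimony / SBML / ODEs`:

1. **Sentence and clause segmentation**, with an abbreviation guard
   ("E. coli" never ends a sentence) and anaphora for bare quantity
   sentences ("The initial concentration is 1 uM" attaches to the most
   recently mentioned species).
2. **Rule matching** producing typed statements: degradation, synthesis,
   conversion (with pathway expansion through intermediates), reversible
   binding, dissociation, catalysis, gene expression, Hill-type regulation,
   initial concentrations.
3. **Rate-law synthesis**: mass action `k·∏[Xᵢ]^νᵢ` for elementary steps,
   irreversible Michaelis–Menten `kcat·E·S/(Km+S)` for catalyzed steps,
   constant synthesis times Hill factors `A²/(K²+A²)` (activation) or
   `K²/(K²+R²)` (repression) for regulated expression. Reversible steps
   split into forward/backward reactions. All generated parameters default
   to 1.0 — realistic values are downstream tuning, not in the text.
4. **Serialization**: deterministic Antimony-subset text and SBML L3V2 XML
   with content-MathML kinetic laws, plus parsers back (full structural
   round trip), and a structural SBML validator (missing required
   attributes, undeclared species, duplicate or malformed ids, missing
   initial state or kinetic law).
5. **Simulation**: `d[Xᵢ]/dt = Σⱼ νᵢⱼ·vⱼ` integrated with a stiff-capable
   adaptive solver (LSODA, rtol 1e-8 / atol 1e-10), with named observables
   (e.g. `Yield = Pfold/(Pfold+Punfold+Punfold_DnaK)`) and CSV export.

Four built-in test problems of increasing size ship as executable fixtures,
and their compiled model sizes are exact:

| problem     | sentences | species | reactions |
|-------------|-----------|---------|-----------|
| decay       | 2         | 1       | 1         |
| hiv         | 5         | 9       | 10        |
| three_step  | 6         | 10      | 15        |
| heat_shock  | 20        | 25      | 50        |

A seeded random-model generator plus a verbalizer close the loop for
property testing: `build(translate(verbalize(m))) ≡ m` structurally.

## Worked example

```python
from kintext import build_model, emit_antimony, model_summary, translate

description = "Protein P decays. The initial concentration is 1 uM."
model = build_model(translate(description), name="decay")
print(model_summary(model))
print(emit_antimony(model))
```

prints

```
(1, 1, 1)
model decay
  // species
  species P;
  // reactions
  J1: P -> ; P*k1;
  // parameter values
  k1 = 1;
  // initial concentrations
  P = 1;
end
```

— one species, one mass-action degradation reaction, the stated 1 uM start.
Simulating with `simulate(model, t_end=10, overrides={"k1": 0.1})` gives
P(10) = 0.367879, the closed form e^(−k·t) at k·t = 1. The same model as
SBML (`write_sbml(model)`) passes the structural validator with zero issues;
deleting any required attribute from the document produces a
`MISSING_REQUIRED_ATTRIBUTE` error.

Or from the shell:

```bash
kintext fixtures --dir fx
kintext translate fx/hiv.txt --format sbml -o hiv.xml
kintext validate hiv.xml
kintext simulate hiv.xml --t-end 50 --override M=2 --override S=10 \
    --override I=1 --observable "Stotal=S+ES" -o hiv.csv
```

Exit codes: 0 ok, 1 I/O, 2 translation, 3 validation, 4 simulation.

The scripts in `examples/` walk through each capability (decay compilation,
HIV proteinase inhibition with conservation checks, the regulated three-step
pathway, heat-shock yield recovery, and the verbalization round trip) and
print what the numbers mean.

## Documentation

`docs/methods.md` describes the conversion-rule semantics, the rate-law
synthesis policy, the fixture designs, numerical choices, and known
limitations.
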