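"""Built-in test problems: four descriptions of increasing complexity.

Each problem ships its description text, the expected model size (species,
reactions) and sentence count, the observables used when simulating it, and
a documented demonstration parameter set. The heat-shock description is a
synthetic transcription of the classic *E. coli* sigma32/DnaK/FtsH circuit
sized to 25 species and 50 reactions; its provenance is flagged in
``fixtures/manifest.json``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import sympy as sp

from .builder import KineticModel, build_model
from .rules import RuleTable, translate
from .simulate import Observable


def _read_fixture(name: str) -> str:
    return resources.files("kintext").joinpath(f"fixtures/{name}").read_text("utf-8")


@dataclass
class TestProblem:
    name: str
    description: str
    expected_species: int
    expected_reactions: int
    expected_sentences: int
    observables: list[Observable] = field(default_factory=list)
    #: Documented demonstration parameter/initial-value overrides producing
    #: the qualitative dynamics discussed for this system. Placeholder-near:
    #: all other parameters stay at the generated default 1.0.
    demo_overrides: dict[str, float] = field(default_factory=dict)
    #: Suggested simulation horizon for the demo overrides.
    demo_t_end: float = 50.0

    def build(self, table: RuleTable | None = None) -> KineticModel:
        """Run the translation pipeline on this description."""
        statements = translate(self.description, table)
        return build_model(statements, name=self.name)


def _s(name: str) -> sp.Symbol:
    return sp.Symbol(name)


def builtin_problems() -> list[TestProblem]:
    """The four shipped test problems (decay, hiv, three_step, heat_shock)."""
    manifest = json.loads(_read_fixture("manifest.json"))

    problems = []
    for name, meta in manifest.items():
        problems.append(TestProblem(
            name=name,
            description=_read_fixture(meta["file"]).strip(),
            expected_species=meta["expected_species"],
            expected_reactions=meta["expected_reactions"],
            expected_sentences=meta["expected_sentences"],
        ))
    by_name = {p.name: p for p in problems}

    by_name["decay"].demo_overrides = {"k1": 0.1}
    by_name["decay"].demo_t_end = 10.0

    hiv = by_name["hiv"]
    hiv.observables = [
        Observable("Stotal", _s("S") + _s("ES")),
        Observable("Ptotal", _s("P") + _s("EP")),
    ]
    # Monomer pool dimerizes into active enzyme; substrate excess; modest
    # inhibitor level so the irreversible EJ sink fills gradually.
    hiv.demo_overrides = {"M": 2.0, "S": 10.0, "I": 1.0}
    hiv.demo_t_end = 50.0

    # Substrate pool large enough that S-induction keeps E1/E2 expressed
    # while accumulating P visibly represses E3 over the run.
    three = by_name["three_step"]
    three.demo_overrides = {"S": 20.0, "kcat1": 0.5, "kcat2": 0.5, "kcat3": 0.5}
    three.demo_t_end = 60.0

    hs = by_name["heat_shock"]
    hs.observables = [
        Observable("Yield",
                   _s("Pfold") / (_s("Pfold") + _s("Punfold") + _s("Punfold_DnaK"))),
        Observable("sigma32_total", _s("sigma32") + _s("sigma32_DnaK") + _s("RNAP_sigma32")),
        Observable("DnaK_total",
                   _s("DnaK") + _s("sigma32_DnaK") + _s("Punfold_DnaK")),
    ]
    # Heat shock at t = 0: the denaturation rate constant k1 jumps to a value
    # that outpaces the basal refolding capacity; heat (held at 1) switches on
    # sigma32 mRNA synthesis, sigma32 accumulates and drives chaperone
    # expression, and the growing DnaK/GroEL pools restore the folded
    # fraction (yield dips to ~0.44 around t = 2 min and recovers above 0.9
    # by ~10 min). Starting pool: 5 uM folded protein; everything not listed
    # stays at the generated default of 1.0.
    hs.demo_overrides = {
        "Pfold": 5.0,   # initial folded protein pool (uM)
        "Heat": 1.0,    # heat signal on from t = 0
        "k1": 0.5,      # elevated denaturation rate (the heat-shock dial, J1)
        "v4": 3.0,      # sigma32-driven DnaK transcription (J4)
        "k5": 3.0,      # DnaK translation (J5)
        "k7": 0.05,     # slow DnaK decay (J7)
        "v8": 2.0,      # sigma32-driven GroEL transcription (J8)
        "k9": 2.0,      # GroEL translation (J9)
        "k11": 0.05,    # slow GroEL decay (J11)
        "k24": 10.0,    # DnaK-mediated refolding (J24)
        "k26": 10.0,    # GroEL-mediated refolding (J26)
        "kf37": 0.05,   # mild FtsH capture of unfolded protein (J37)
        "kf39": 0.05,   # mild HslVU capture of unfolded protein (J39)
        "v41": 0.05,    # slow synthesis of new protein (J41)
        "k42": 0.5,     # maturation of nascent protein (J42)
        "k43": 0.2,     # sigma32 mRNA turnover (J43)
    }
    hs.demo_t_end = 200.0
    return problems


def get_problem(name: str) -> TestProblem:
    for p in builtin_problems():
        if p.name == name:
            return p
    raise KeyError(name)
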