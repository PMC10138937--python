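{
  "decay": {
    "file": "decay.txt",
    "expected_species": 1,
    "expected_reactions": 1,
    "expected_sentences": 2,
    "provenance": "verbatim two-sentence decay description"
  },
  "hiv": {
    "file": "hiv.txt",
    "expected_species": 9,
    "expected_reactions": 10,
    "expected_sentences": 5,
    "provenance": "authored to the narrated HIV proteinase mechanism (2M<=>E; E+S<=>ES; ES->E+P; E+P<=>EP; E+I<=>EI; EI->EJ); reversible steps count as two reactions"
  },
  "three_step": {
    "file": "three_step.txt",
    "expected_species": 10,
    "expected_reactions": 15,
    "expected_sentences": 6,
    "provenance": "authored: S->M1->M2->P with Michaelis-Menten enzymes E1-E3, a four-reaction expression unit per enzyme, and three gene regulations (P represses E3)"
  },
  "heat_shock": {
    "file": "heat_shock.txt",
    "expected_species": 25,
    "expected_reactions": 50,
    "expected_sentences": 20,
    "provenance": "synthetic: authored 20-sentence E. coli heat shock response description (sigma32 mRNA heat activation, sigma32-driven DnaK/GroEL/FtsH/HslVU expression, DnaK- and GroEL-mediated refolding of Punfold, FtsH-mediated sigma32 degradation, RNAP/sigma70 competition) sized to 25 species and 50 reactions"
  }
}
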