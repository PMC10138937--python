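Protein P decays. The initial concentration is 1 uM.
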