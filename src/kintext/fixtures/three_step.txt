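Substrate S is converted into product P through intermediates M1 and M2. The metabolic reactions are catalyzed by three enzymes, E1, E2, and E3. The enzymes E1, E2, and E3 are expressed. S activates the expression of E1. S activates the expression of E2. The accumulated P represses the expression of E3.
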