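Two monomers M bind to form an active enzyme E. The enzyme E can bind to the substrate S to form the complex ES, and the enzyme E can bind to the product P to form the complex EP. The complex ES is converted into the enzyme E and the product P. The enzyme E can bind to the inhibitor I to form the complex EI. The complex EI is then converted into the irreversible complex EJ.
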