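The folded protein Pfold is converted into the unfolded protein Punfold. The mRNA mRNA_sigma32 is synthesized. Heat activates the synthesis of mRNA_sigma32. σ32 is synthesized from mRNA_sigma32. The chaperones DnaK and GroEL, the protease FtsH, and the protease HslVU are expressed. σ32 activates the expression of DnaK, GroEL, FtsH, and HslVU. σ32 and DnaK can bind to form the complex sigma32_DnaK. σ32 is degraded by the protease FtsH. The complex sigma32_DnaK is degraded by the protease FtsH. The unfolded protein Punfold and the chaperone DnaK can bind to form the complex Punfold_DnaK. The complex Punfold_DnaK is converted into Pfold and DnaK. Punfold and the chaperone GroEL can bind to form the complex Punfold_GroEL. The complex Punfold_GroEL is converted into Pfold and GroEL. The sigma factor σ70 and the polymerase RNAP are expressed. σ32 and RNAP can bind to form the holoenzyme RNAP_sigma32. σ70 and RNAP can bind to form the holoenzyme RNAP_sigma70. Punfold and the protease FtsH can bind to form the complex Punfold_FtsH. The complex Punfold_FtsH is converted into FtsH. Punfold and the protease HslVU can bind to form the complex Punfold_HslVU. The complex Punfold_HslVU is converted into HslVU, the nascent protein Pnew is synthesized from RNAP_sigma70, Pnew is converted into Pfold, and mRNA_sigma32 degrades.
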