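# Synthetic placeholder alert set (over-halogenation-style motifs).
[Cl][CX4]([Cl])[Cl]	trichloromethyl
[I]	iodine
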