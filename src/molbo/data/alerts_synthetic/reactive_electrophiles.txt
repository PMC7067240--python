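# Synthetic placeholder alert set (reactive-electrophile-style motifs).
[CX3](=O)[Cl,Br,I]	acyl halide
C1OC1	epoxide
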