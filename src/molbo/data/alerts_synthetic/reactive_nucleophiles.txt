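# Synthetic placeholder alert set (reactive-nucleophile-style motifs).
[SX2H]	thiol
[NX3][NX3]	hydrazine
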