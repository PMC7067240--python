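# Synthetic placeholder alert set (promiscuous-binder-style motifs).
[CX3H1]=O	aldehyde
[CX3](=O)[CX3](=O)	1,2-dicarbonyl
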