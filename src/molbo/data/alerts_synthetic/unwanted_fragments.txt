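# Synthetic placeholder alert set (unwanted-fragment-style motifs).
[SX2][SX2]	disulfide
[OX2][OX2]	peroxide
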