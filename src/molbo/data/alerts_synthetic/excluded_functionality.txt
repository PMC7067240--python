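# Synthetic placeholder alert set (excluded-functionality-style motifs).
[N+](=O)[O-]	nitro group
[N;X2]=[N;X1]	diazo
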