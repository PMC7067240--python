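# Synthetic placeholder alert set (unstable-group-style motifs).
[N]=[N]=[N]	azide
C=C=C	allene
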