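# Synthetic placeholder alert set (assay-interference-style nuisance motifs).
# Not a redistribution of any curated collection.
[OX1]=[CX3]-[CX3]=[CX3]	enone Michael acceptor
c1ccc2c(c1)C(=O)c1ccccc1C2=O	anthraquinone core
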