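g00000
g00040
g00080
g00120
g00160
g00200
g00240
g00280
not_a_gene
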