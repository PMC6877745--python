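domain	codon_start	codon_end
RING	53	122
ARD	439	559
BRCT	560	777
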