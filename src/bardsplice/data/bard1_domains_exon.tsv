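domain	exon_start	exon_end
RING	2	3
ARD	5	7
BRCT	8	11
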