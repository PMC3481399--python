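drug	protein	pmid	direction
Tamoxifen	ESR1_HUMAN	14507640	-1
Tamoxifen	ESR1_HUMAN	2359140	-1
Tamoxifen	ESR1_HUMAN	14759988	-1
Tamoxifen	ESR1_HUMAN	11774281	-1
Tamoxifen	ESR1_HUMAN	2137212	-1
Tamoxifen	ESR1_HUMAN	9328205	-1
Tamoxifen	ESR1_HUMAN	11261829	-1
Tamoxifen	ESR1_HUMAN	12767276	1
Tamoxifen	ESR1_HUMAN	11812086	1
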