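drug	protein	r_p	direction
Tamoxifen	AKT1_HUMAN	82.99	1
Tamoxifen	BRCA2_HUMAN	21.14	1
Tamoxifen	CADH1_HUMAN	17.57	1
Tamoxifen	CDK2_HUMAN	2.94	1
Tamoxifen	E2F1_HUMAN	2.95	1
Tamoxifen	ERBB2_HUMAN	2.07	1
Tamoxifen	ESR1_HUMAN	72.39	-1
Tamoxifen	IRS1_HUMAN	2.51	-1
Tamoxifen	JUN_HUMAN	2.91	1
Tamoxifen	MYC_HUMAN	3.49	1
Tamoxifen	NCOA3_HUMAN	2.61	-1
Tamoxifen	NCOR1_HUMAN	2.81	1
Tamoxifen	P53_HUMAN	169.82	-1
Tamoxifen	P85A_HUMAN	2.92	1
Tamoxifen	PTEN_HUMAN	3.98	1
Plicamycin	MYC_HUMAN	3.49	-1
Plicamycin	SP1_HUMAN	3.32	-1
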