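gene	status
AKT1_HUMAN	unchanged
BRCA2_HUMAN	unchanged
CADH1_HUMAN	unchanged
CDK2_HUMAN	unchanged
E2F1_HUMAN	unchanged
ERBB2_HUMAN	over
ESR1_HUMAN	over
IRS1_HUMAN	unchanged
JUN_HUMAN	under
MYC_HUMAN	under
NCOA3_HUMAN	unchanged
NCOR1_HUMAN	unchanged
P53_HUMAN	unchanged
P85A_HUMAN	unchanged
PTEN_HUMAN	unchanged
SP1_HUMAN	unchanged
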