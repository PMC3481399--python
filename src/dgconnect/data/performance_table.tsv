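cancer	sensitivity	specificity	acc	ppv	f_score
Bladder	80.84	87.11	86.70	30.51	44.30
Breast	79.80	84.91	84.27	43.01	55.89
Leukemia	83.16	86.11	85.63	53.39	65.03
Lung	78.44	89.37	87.86	54.06	64.01
Lymphoma	81.20	87.60	86.78	48.92	61.05
Melanoma	77.39	91.53	90.17	49.24	60.19
Ovary	80.88	84.34	84.09	28.84	42.52
Pancreas	84.99	86.45	86.34	33.82	48.38
Prostate	82.84	88.38	87.93	38.88	52.92
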