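protein1	protein2	combined_score
PCSK9	HMGCR	0.999
PCSK9	MTTP	0.982
PCSK9	APOC3	0.965
PCSK9	LPA	0.948
PCSK9	CETP	0.931
PCSK9	APOB	0.92
HMGCR	MTTP	0.913
HMGCR	APOC3	0.904
HMGCR	LPA	0.885
HMGCR	CETP	0.852
HMGCR	APOB	0.821
MTTP	APOC3	0.79
MTTP	LPA	0.752
MTTP	CETP	0.711
MTTP	APOB	0.662
APOC3	LPA	0.613
APOC3	CETP	0.564
APOC3	APOB	0.513
LPA	CETP	0.462
LPA	APOB	0.411
CETP	APOB	0.213
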