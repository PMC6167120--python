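# Bacterial SSU rRNA primer panel for LNA-clamping PCR, with reported
# properties: published Tm range endpoints (deg C) and annealing-site
# coordinates in E. coli 16S numbering (1-based, inclusive; reverse primers
# list the 5' coordinate first, hence descending).
name	sequence	orientation	tm_min_c	tm_max_c	pos_5prime	pos_3prime
modified_63f	YRKGCYTWAYACATGCAAGTC	forward	58	67	43	63
KU63f	GCYTWAYACATGCAAGTC	forward	54	60	46	63
KU64f	GCYTWAYACATGCAAGTCG	forward	57	62	46	64
KU68f	AYACATGCAAGTCGARCG	forward	58	64	51	68
1492r	GGYTACCTTGTTACGACTT	reverse	57	60	1510	1492
KU1494r	GGYTACCTTGTTACGAC	reverse	55	58	1510	1494
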