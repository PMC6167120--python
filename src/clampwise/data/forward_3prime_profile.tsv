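# Reported per-phylum per-base match percentages (%) at the 3'-end region of
# the 63f-family forward bacterial SSU rRNA primers, E. coli 16S positions
# 60-68.  The "base" row gives the primer symbol at each position.
phylum	60	61	62	63	64	65	66	67	68
base	A	G	T	C	G	A	R	C	G
Proteobacteria	92.8	93.9	94.4	94.3	94.6	87.1	94.1	94.2	94.7
Firmicutes	85.8	87.4	87.7	82.5	90.1	86.6	90.4	86.3	84.7
Actinobacteria	94.7	95.3	95.8	95.6	96.1	95.1	96.4	96.7	97.1
Acidobacteria	81.3	84.8	84.8	86.1	86.1	59.1	88.7	86.1	87.0
Bacteroidetes	89.0	92.9	83.3	93.1	93.6	85.6	93.9	38.9	95.4
Chloroflexi	88.5	92.3	91.3	91.3	92.8	73.6	91.8	92.3	91.8
TM7	86.9	86.4	92.8	87.7	90.3	84.7	90.7	85.2	89.8
TM6	58.3	60.4	58.3	58.3	59.4	59.4	60.4	58.3	59.4
Verrucomicrobia	85.9	87.6	88.0	86.7	88.4	79.5	87.6	87.6	88.0
Planctomycetes	53.3	93.1	93.7	93.3	96.2	37.4	96.0	85.1	83.8
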