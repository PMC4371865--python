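codon	amino_acid	usage_per_1000	rrt_pos6	p_value
CTC	Leu	5.4	1.89	0.0001
CCC	Pro	6.8	1.71	0.0001
GGG	Gly	6.0	1.61	0.0001
AGG	Arg	9.2	1.59	0.0001
ATA	Ile	17.8	1.57	0.0001
GGA	Gly	10.9	1.56	0.0001
TGG	Trp	10.4	1.53	0.0001
GTG	Val	10.8	1.52	0.0001
CGC	Arg	2.6	1.45	0.0001
CGA	Arg	3.0	1.45	0.0008
CGG	Arg	1.7	1.44	0.0010
TCG	Ser	8.6	1.43	0.0001
CCA	Pro	18.3	1.38	0.0001
ACA	Thr	17.8	1.35	0.0001
CCG	Pro	5.3	1.31	0.0001
GTA	Val	11.8	1.31	0.0001
GCA	Ala	16.2	1.28	0.0001
CCT	Pro	13.5	1.27	0.0001
TCA	Ser	18.7	1.26	0.0001
TAC	Tyr	14.8	1.25	0.0001
TAT	Tyr	18.8	1.25	0.0001
GAG	Glu	19.2	1.25	0.0001
CTA	Leu	13.4	1.25	0.0001
CTT	Leu	12.3	1.24	0.0001
TGC	Cys	4.8	1.23	0.0001
GGC	Gly	9.8	1.22	0.0001
CAG	Gln	12.1	1.15	0.0002
ACG	Thr	8.0	1.12	0.0069
AGT	Ser	14.2	1.10	0.0060
AGC	Ser	9.8	1.09	0.0213
CAC	His	7.8	1.08	0.0098
TTT	Phe	26.1	1.05	0.0529
GAA	Glu	45.6	1.04	0.0538
AGA	Arg	21.3	1.01	0.3014
TTC	Phe	18.4	1.00	0.4955
GCG	Ala	6.2	0.99	0.4650
TCC	Ser	14.2	0.99	0.3341
TTA	Leu	26.2	0.99	0.3166
TCT	Ser	23.5	0.98	0.2249
CAT	His	13.6	0.93	0.0188
GGT	Gly	23.9	0.93	0.0003
ATG	Met	20.9	0.92	0.0027
ATT	Ile	30.1	0.92	0.0005
TTG	Leu	27.2	0.92	0.0001
CTG	Leu	10.5	0.92	0.0139
AAT	Asn	35.7	0.88	0.0001
AAA	Lys	41.9	0.88	0.0003
CGT	Arg	6.4	0.87	0.0002
CAA	Gln	27.3	0.87	0.0001
GCC	Ala	12.6	0.86	0.0001
GAC	Asp	20.2	0.85	0.0001
TGT	Cys	8.1	0.81	0.0001
GCT	Ala	21.2	0.81	0.0001
ATC	Ile	17.2	0.80	0.0001
ACT	Thr	20.3	0.78	0.0001
GAT	Asp	37.6	0.76	0.0001
AAC	Asn	24.8	0.76	0.0001
GTT	Val	22.1	0.75	0.0001
GTC	Val	11.8	0.75	0.0001
AAG	Lys	30.8	0.74	0.0001
ACC	Thr	12.7	0.70	0.0001
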