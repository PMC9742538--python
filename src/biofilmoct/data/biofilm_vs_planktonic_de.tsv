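# Differential gene expression of S. saccharolyticus 13T0028, biofilm vs planktonic cells at 48 h.
# Published result table (genes with log2-fold change >2 or <-2); values as printed (1 decimal).
locus_tag	annotation	mean_expression	log2fc
DMB76_004255	hypothetical protein	374.6	3.4
DMB76_009105	epsilon family phenol-soluble modulin	47.5	3.4
DMB76_001650	aspartate 1-decarboxylase	1268.5	3.0
DMB76_000275	hypothetical protein	8801.7	2.8
DMB76_011400	type I toxin-antitoxin system Fst family toxin	29.8	2.7
DMB76_011110	GlsB/YeaQ/YmgE family stress response membrane protein	8802.0	2.6
DMB76_000660	ABC transporter ATP-binding protein	33.8	2.6
DMB76_008440	gallidermin family lantibiotic	105.0	2.4
DMB76_010640	septum formation initiator family protein	742.6	2.3
DMB76_001580	LPXTG cell wall anchor domain-containing protein	472.1	2.3
DMB76_002575	hypothetical protein	10332.9	2.3
DMB76_000380	MptD family putative ECF transporter S component	163.7	2.3
DMB76_009220	DUF4887 domain-containing protein	3417.0	2.3
DMB76_004810	type I toxin-antitoxin system Fst family toxin	42.5	2.2
DMB76_001590	hypothetical protein	59.8	2.2
DMB76_001620	L-lactate dehydrogenase	59345.1	2.2
DMB76_001350	DegT/DnrJ/EryC1/StrS family aminotransferase	31127.7	2.1
DMB76_008990	MetQ/NlpA family ABC transporter substrate-binding protein	9714.4	2.1
DMB76_002130	hypothetical protein	1654.6	2.1
DMB76_005335	universal stress protein	6535.2	2.1
DMB76_001480	hypothetical protein	22065.1	2.1
DMB76_001355	LCP family protein	28412.8	2.1
DMB76_002790	SDR family oxidoreductase	198300.7	2.0
DMB76_001345	acetyltransferase	11672.2	2.0
DMB76_008980	CsbD family protein	280.0	2.0
DMB76_002785	amidohydrolase	97240.6	2.0
DMB76_001640	3-methyl-2-oxobutanoate hydroxymethyltransferase	8016.6	2.0
DMB76_007480	DNA-protecting protein DprA	37.7	-2.1
DMB76_008220	hypothetical protein	5.7	-2.1
DMB76_004380	DUF3267 domain-containing protein	104.6	-2.1
DMB76_002540	copper resistance protein CopC	94.3	-2.1
DMB76_006500	class I SAM-dependent RNA methyltransferase	1274.6	-2.2
DMB76_000990	intracellular adhesion protein D	7.0	-2.4
DMB76_009775	Bax inhibitor-1/YccA family protein	155.8	-2.5
DMB76_010290	deoxynucleoside kinase	172.0	-2.6
DMB76_001160	Csa1 family protein	5.7	-2.7
DMB76_006280	DUF309 domain-containing protein	119.9	-2.8
DMB76_010395	class I SAM-dependent methyltransferase	529.3	-2.8
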