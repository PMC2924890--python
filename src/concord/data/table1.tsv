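protein_acc	protein_name	prot_fc_skf	prot_fc_ly	mrna_acc	mrna_name	mrna_fc_skf	mrna_fc_ly	starred
AAW82445	14 kDa apolipoprotein	-1.3		CA967592	14 kda apolipoprotein	-1.6		True
AAW82445	14 kDa apolipoprotein		-1.5	CF662502	14 kda apolipoprotein		1.9	True
CAG00145	25 kDa synaptosomal-associated protein		-1.5	CA969142	synaptosomal-associated protein 25		1.4	False
NP_956213	adaptor-related protein complex 2, beta 1 subunit	1.3						False
AAH83251	Atp2b4 protein		1.4					False
AAZ38450	beta thymosin-like protein		-1.3					False
AAF79948	brain-type fatty-acid binding protein; B-Fabp		-1.4					False
CAK04737	calbindin 2, like	-1.2						False
NP_001017741	calcium/calmodulin-dependent protein kinase II alpha	2.3	1.8					False
Q71UH6	Calmodulin		-1.2	CA969795	calmodulin variant 1		1.4	False
CAF92971	Creatine kinase, brain		-1.4					False
NP_942096	creatine kinase, mitochondrial 1		1.2					False
CAK10905	cytochrome c oxidase subunit IV isoform 1	1.2						False
AAV52802	glutamine synthetase	1.4	-1.3	FG393017	glutamine synthetase	1.9		False
ABD67511	glutathione S-transferase rho	-1.3	-1.2	CA964231	glutathione S-transferase rho	-1.6		False
AAV52803	glyceraldehyde-3-phosphate dehydrogenase	-1.4		DY231775	GAPDH	1.6		False
AAA21578	kainate receptor alpha subunit	1.8	1.3	FG392717	kainate receptor alpha subunit	1.4		False
AAH63955	Krt5 protein		2.6					False
AAM21708	liver-basic fatty acid binding protein		3.6	CA968596	fatty acid binding protein liver basic		1.4	True
AAM21708	liver-basic fatty acid binding protein	8.6		CA970443	fatty acid binding protein liver basic	-1.5		True
NP_956241	malate dehydrogenase 1a, NAD (soluble)	1.2		CA964750	malate dehydrogenase nad	2.0	1.3	False
ABC69306	myoglobin isoform 2	-1.4		CA968088	myoglobin		1.4	False
NP_958898	N-ethylmaleimide-sensitive factor		1.3	FG392958	n-ethylmaleimide-sensitive factor	1.4		False
CAN88379	novel protein sim to vert EF hand calcium binding protein 2 (EFCBP2)		-1.1					False
CAK05381	parvalbumin		-1.1	CA969705	parvalbumin		1.5	False
ABF57553	Pi-class glutathione S-transferase	-1.7	-1.6					False
BAA78376	polypeptide elongation factor 1 alpha	1.3		CA967511	eukaryotic translation elongation factor 1 alpha 1	-1.8		False
XP_001340376	PREDICTED: myelin basic protein isoform 3	-3.9		CA967910	myelin basic protein	2.0		False
CAF98839	PREDICTED: similar to germinal histone H4 gene		-1.1					False
XP_001338014	PREDICTED: similar to microtubule-associated protein 1 A		1.4					False
XP_696230	PREDICTED: similar to microtubule-associated protein tau	-1.1		CA967834	microtubule-associated protein tau	1.9		False
XP_001335551	PREDICTED: similar to Myelin basic protein	-1.5	-1.5					False
XP_691535	PREDICTED: similar to Nj-synaphin 2		-2.2					False
CAF95822	Putative histone cluster 1, H2bb	-1.6	-1.5					False
AAG14350	putative oncoprotein nm23	-1.3		CA964203	non-metastatic cells 2, protein (NM23B)	-1.6		False
AAI14255	short chain dehydrogenase/reductase	-1.9	-1.5	CA968680	dehydrogenase reductase sdr family member 12		1.3	False
NP_001091958	spectrin alpha 2	1.3		FG392760	spectrin alpha 2	1.4		False
NP_001017850	stathmin 1/oncoprotein 18		-1.3	CA969799	stathmin 1 oncoprotein 18 variant 8		1.4	True
NP_001017850	stathmin 1/oncoprotein 18	-1.5		CA966170	stathmin 1 oncoprotein 18 variant 8	1.5		True
NP_001018488	synuclein, gamma b (breast cancer-specific protein 1)	-1.5						False
AAM90972	transferrin variant A1	1.5		CA968595	transferrin variant c	1.9		False
AAM90973	transferrin variant B1		-1.9					False
NP_705954	triosephosphate isomerase 1b	-1.3	-1.2	CA968504	triosephosphate isomerase 1b	1.8		False
NP_997770	tyrosine 3-/tryptophan 5-monooxygenase activation protein, epsilon polypeptide	1.1						False
AAQ94569	ubiquitin C	-1.3						False
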