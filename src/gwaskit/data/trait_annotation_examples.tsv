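# Curated reference set of scored trait annotations: phenotype trait values
# matched against ontology term labels, with the match basis (P = preferred
# label, S = synonym), the word-alignment match_score, the per-ontology
# suitability and acceptance in effect, and the resulting annotation_score
# (rounded to 2 decimals). Abbreviated display forms are expanded to full
# words. Used to recover the default annotation-score weights by least
# squares and as worked examples for the alignment scorer.
query	ontology	ontology_id	pref_label	matched_label	basis	match_score	onto_suitability	onto_acceptance	annotation_score
creatinine measurement	NCIT	NCIT_C64547	Creatinine Measurement	Creatinine Measurement	P	10	4.39	0.86	5.23
creatinine measurement	NCIT	NCIT_C61048	Urine Creatinine Measurement	Urine Creatinine Measurement	P	9	4.39	0.86	4.71
mean arterial pressure	NCIT	NCIT_C120935	Mean Pulmonary Arterial Pressure	Mean Pulmonary Arterial Pressure	P	9	4.39	0.86	4.71
diverticulitis	EFO	EFO_1001460	diverticulitis	diverticulitis	P	10	3.40	0.32	3.36
survival time	EFO	EFO_0000714	survival time	survival time	P	10	3.40	0.32	3.36
diastolic blood pressure	EFO	EFO_0006336	diastolic blood pressure	diastolic blood pressure	P	10	3.40	0.32	3.36
viral load	EFO	EFO_0010125	viral load	viral load	P	10	3.40	0.32	3.36
mean corpuscular hemoglobin	EFO	EFO_0004527	mean corpuscular hemoglobin	mean corpuscular hemoglobin	P	10	3.40	0.32	3.36
calcium measurement	EFO	EFO_0004838	calcium measurement	calcium measurement	P	10	3.40	0.32	3.36
autoimmune disease	EFO	EFO_0005140	autoimmune disease	autoimmune disease	P	10	3.40	0.32	3.36
moderate albuminuria	HP	HP_0012594	Moderate albuminuria	Moderate albuminuria	P	10	3.40	0.32	3.36
glomerular filtration rate	EFO	EFO_0005208	glomerular filtration rate	glomerular filtration rate	P	10	3.40	0.32	3.36
anxiety	EFO	EFO_0005230	anxiety	anxiety	P	10	3.40	0.32	3.36
diaphragmatic hernia	EFO	EFO_0007216	congenital diaphragmatic hernia	congenital diaphragmatic hernia	P	9	3.40	0.32	3.02
sarcoidosis	EFO	EFO_0010723	ocular sarcoidosis	ocular sarcoidosis	P	9	3.40	0.32	3.02
sneeze	EFO	EFO_0007887	autosomal dominant compelling helio-ophthalmic outburst syndrome	Peroutka sneeze	S	8	3.40	0.32	2.69
anorexia nervosa	HP	HP_0002039	Anorexia	Anorexia	P	8	3.40	0.32	2.69
lean body mass	NCIT	NCIT_C139219	Lean Body Mass to Total Body Mass Ratio	Lean Body Mass to Total Body Mass Ratio	P	5	4.39	0.86	2.62
fasting blood insulin measurement	EFO	EFO_0004465	fasting blood glucose measurement	fasting blood glucose measurement	P	7.5	3.40	0.32	2.52
protozoal diseases	MONDO	MONDO_0001955	protozoal dysentery	protozoal dysentery	P	7.5	3.40	0.26	2.43
primary sclerosing	EFO	EFO_0004268	sclerosing cholangitis	sclerosing cholangitis	P	7	3.40	0.32	2.35
event free survival time	EFO	EFO_0004919	metastasis free survival	metastasis free survival time	S	6.5	3.40	0.32	2.18
response to vancomycin	NCIT	NCIT_C76312	Vancomycin Resistant Enterococcus	Vancomycin Resistant Enterococcus	P	4	4.39	0.86	2.09
fish oil supplement exposure measurement	EFO	EFO_0009116	vitamin supplement exposure measurement	vitamin supplement exposure measurement	P	5.5	3.40	0.32	1.85
magnesium:creatinine ratio measurement	EFO	EFO_0007635	concentration dose ratio	CDR measurement	S	4.5	3.40	0.32	1.51
other and unspecified	EFO	EFO_0009734	unspecified juvenile idiopathic arthritis	unspecified JIA	S	4	3.40	0.32	1.34
pre-eclampsia	DOID	DOID_10591	pre-eclampsia	pre-eclampsia	P	10	0.14	0.39	0.89
bipolar disorder	DOID	DOID_3312	bipolar disorder	bipolar disorder	P	10	0.09	0.39	0.85
binocular movement	MP	MP_0006148	binocular blindness	binocular blindness	P	7.5	0.59	0.28	0.77
asthma	HP	HP_0002099	Asthma	Asthma	P	10	0.16	0.31	0.75
stroke	SYMP	SYMP_0000734	stroke	stroke	P	10	0.10	0.25	0.58
schizophrenia	OMIT	OMIT_0013465	Schizophrenia, Paranoid	Schizophrenia, Paranoid	P	9	0.27	0.18	0.52
schizophrenia	OMIT	OMIT_0013464	Schizophrenia, Disorganized	Schizophrenia, Disorganized	P	9	0.27	0.18	0.52
creatinine measurement	MAXO	MAXO_0000832	serum creatinine measurement	serum creatinine measurement	P	9	0.31	0.13	0.46
bipolar disorder	NBO	NBO_0000258	bipolar disorder	bipolar disorder	P	10	0.08	0.19	0.44
postydysenteric arthropathy	MPATH	MPATH_684	arthropathy	arthropathy	P	8	0.05	0.19	0.34
inflammatory biomarker measurement	MAXO	MAXO_0000554	interleukin-1 beta biomarker measurement	interleukin-1 beta biomarker measurement	P	6.5	0.31	0.13	0.33
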