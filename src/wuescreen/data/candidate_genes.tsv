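# Candidate genes of the water-use-efficiency matrix-correlation screen (P < 0.01),
# with their Mantel coefficients, permutation P values, functional categories and
# differential-expression calls between the native (JH) and semiarid (QG) sites.
# Category labels map the published category names as follows:
#   Photosynthesis        <- "Photosynthesis"
#   StomatalRegulation    <- "Stomatal regulation"
#   AbioticStress         <- "Abiotic stress responses"
#   ProteinMetabolism     <- "Protein metabolism"
#   Others                <- "Others"
# de_direction: up / down when the gene is significantly differentially expressed
# (BH-adjusted P < 0.05, QG vs JH), none otherwise; de_adj_p is blank for "none".
# Notes record id/category discrepancies between the published tables; the candidate
# list is taken as authoritative for ids and the categorization table for categories.
gene_id	mantel_r	p_value	category	de_direction	de_adj_p	annotation	note
MluLR14810	0.429	0.001	Photosynthesis	up	4.46E-04	Photosystem II reaction centre protein K (PsbK)
MluLR13061	0.363	0.001	AbioticStress	none		Lysine-specific histone demethylase 1 (LSD1)
MluLR17433	0.361	0.001	Photosynthesis	up	1.43E-04	Photosystem II reaction centre protein I (PsbI)
MluLR5439	0.351	0.001	Others	none		Hypothetical protein
MluLR10901	0.348	0.001	ProteinMetabolism	none		Ammonium transporter 2 (AMT2)
MluLR18372	0.343	0.001	Others	down	8.79E-11	Hypothetical protein
MluLR5367	0.339	0.002	Others	none		Hypothetical protein
MluLR17105	0.318	0.002	ProteinMetabolism	up	2.11E-06	Ribosomal protein S4
MluLR16034	0.316	0.004	AbioticStress	none		Cyclophilin type peptidyl-prolyl cis-trans isomerase
MluLR14116	0.316	0.002	Others	none		Hypothetical protein
MluLR8003	0.313	0.003	StomatalRegulation	none		Cysteine-rich receptor-like protein kinase 10-like (CRK10-like)
MluLR15213	0.312	0.003	AbioticStress	none		Prolyl 4-hydroxylase alpha-2 subunit (P4HA1)
MluLR12315	0.311	0.010	AbioticStress	none		Methyltransferase-like protein 2-like (Mettl2-like)
MluLR8832	0.309	0.002	StomatalRegulation	none		Hydroxyacid oxidase 1 (HAO1)
MluLR17106	0.308	0.004	Photosynthesis	up	5.29E-13	Photosystem I assembly protein Ycf4, photosystem I subunit VIII (PsaI)
MluLR14298	0.306	0.007	Others	none		Transcription factor E2F3
MluLR10824	0.305	0.003	Others	none		Hypothetical protein
MluLR16796	0.305	0.005	Photosynthesis	none		Chloroplast envelope membrane protein-like (CemA-like)
MluLR2994	0.302	0.001	AbioticStress	none		Alcohol dehydrogenase-like 5-like (ADH5-like)
MluLR5858	0.300	0.004	StomatalRegulation	none		WUSCHEL-related homeobox 14 (WOX14)
MluLR14458	0.299	0.001	StomatalRegulation	none		Auxin response factor 4 (ARF4)
MluLR18370	0.296	0.005	Others	down	4.46E-15	Isoaspartyl peptidase/L-asparaginase 1-like (ASRGL1-like)
MluLR11713	0.293	0.003	Others	none		Unknown
MluLR3563	0.289	0.002	Others	down	5.37E-05	Hypothetical protein
MluLR3628	0.288	0.007	ProteinMetabolism	down	6.68E-06	ORMDL family protein
MluLR1213	0.288	0.006	Others	none		Hypothetical protein
MluLR17104	0.287	0.001	ProteinMetabolism	none		Ribosomal protein S16
MluLR17108	0.276	0.007	Photosynthesis	up	2.33E-11	Photosystem II reaction centre protein H (PsbH)
MluLR11870	0.276	0.008	AbioticStress	none		SRG1-like protein
MluLR9412	0.272	0.002	Others	none		Unknown
MluLR4945	0.263	0.009	AbioticStress	up	6.12E-08	Lecithin-cholesterol acyltransferase-like 1-like (LCAT1-like)	DE table lists this gene under Others with annotation Hypothetical protein
MluLR5294	0.261	0.005	StomatalRegulation	up	1.25E-16	Anion transporter 4 (OAT4)
MluLR8498	0.259	0.007	Others	none		Unknown
MluLR2876	0.259	0.003	StomatalRegulation	up	1.12E-06	Ubiquitin-protein ligase E3 (UBE3)
MluLR18313	0.257	0.009	AbioticStress	none		18.8kDa class V heat shock protein (HSP18.8)
MluLR7126	0.256	0.010	StomatalRegulation	none		Starch synthase II-2
MluLR15163	0.253	0.008	Photosynthesis	none		Thioredoxin-like
MluLR4277	0.252	0.010	Photosynthesis	none		Pyruvate orthophosphate dikinase regulatory protein (PDRP)
MluLR420	0.252	0.010	Others	none		DNA topoisomerase 2-binding protein 1 (TOPBP1)
MluLR12213	0.251	0.009	StomatalRegulation	none		Hexose carrier protein 6 (HEX6)
MluLR12611	0.250	0.008	AbioticStress	none		Methyl-CpG binding domain106
MluLR17402	0.246	0.008	Photosynthesis	up	3.86E-04	Plastocyanin (petE)
MluLR18082	0.242	0.007	Others	down	4.65E-05	Hypothetical protein	DE table lists this gene id as MluLR18102; the candidate-list id is recorded here
MluLR15146	0.242	0.006	AbioticStress	up	8.60E-03	FKBP-type peptidyl-prolyl cis-trans isomerase 4
MluLR16886	0.241	0.007	StomatalRegulation	none		WRKY transcription factor 4 (WRKY4)
MluLR4566	0.235	0.006	AbioticStress	none		DEAD-box ATP-dependent RNA helicase 57-like (RH57-like)
MluLR17624	0.234	0.010	AbioticStress	none		RLC retrotransposon
MluLR4148	0.232	0.008	Others	none		Hypothetical protein
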