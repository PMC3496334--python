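# Literature measurements of cytoplasmic diffusion in E. coli used to
# calibrate the scale-dependent viscosity reference curve.
# ln_ratio = ln(eta_eff/eta_0) = ln(D0/Dcyto) for each probe.
# The source column groups rows by the original measurement study.
name	mass_kda	radius_nm	ln_ratio	source
Water	0.018	0.16	0.1	study-17
Glucose	0.423	0.53	2.1	study-28
mEos2	26	2.8	2.1	study-12
EYFP	27	2.8	2.4	study-23
GFP	27	2.8	2.4	study-11
GFP	27	2.8	3.2	study-11
GFP	27	2.8	2.2	study-41
GFP	27	2.8	2.6	study-37
GFP	27	2.8	2.3	study-30
GFP	27	2.8	3.2	study-28
GFP	27	2.8	2.7	study-21
GFP-His6	28	2.8	3.1	study-11
torA-GFP	30	2.9	2.5	study-29
CheY-GFP	41	3.3	2.8	study-06
NlpA-GFP	55	3.7	3.4	study-30
NlpA(ss)-GFP	55	3.7	3.2	study-30
torA-GFP2	57	3.8	2.2	study-30
torA-GFP2	57	3.8	2.1	study-30
AmiA-GFP	58	3.8	3.6	study-30
AmiA-GFP	58	3.8	3.6	study-30
AmiA(ss)-GFP	58	3.8	2.2	study-30
CFP-CheW-YFP	71	4.1	3.5	study-23
cMBP-GFP	72	4.1	3.2	study-11
torA-GFP3	84	4.4	2.2	study-30
CFP-CheR-YFP	86	4.4	3.3	study-23
torA-GFP4	111	4.9	2.2	study-30
torA-GFP5	138	5.3	2.8	study-30
(beta-Gal-GFP)4	582	9.4	3.5	study-28
Ribosome 70S	2500	16.6	6.0	study-02
mRNA-GFP	6000	21.3	6.2	study-13
Plasmid-GFP	18480	203.9	10.1	study-04
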