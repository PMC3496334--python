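# Published cytoplasmic diffusion coefficients for reference molecules in
# E. coli (small molecules via van der Waals radii, proteins and ribosomes
# via the protein scaling law).  Used to recover the original study's
# unrounded cytoplasm calibration; see sdvrc.fitting.ecoli_reference_calibration.
name	molecule_class	radius_nm	Dcyto_um2s
Guanine	small_molecule	0.29	539
Histidine	small_molecule	0.32	478
Galactose	small_molecule	0.33	458
Arginine	small_molecule	0.34	428
Lactose	small_molecule	0.41	328
ATP	small_molecule	0.43	302
TrpR-Monomer	protein	2.1	19.71
TrpR-Dimer	protein	2.7	10.92
LacI-Monomer	protein	3.2	7.28
LacI-Tetramer	protein	5.6	1.79
RNAP Holoenzyme	protein	8.5	0.5
Ribosome 30S	protein	11.6	0.18
Ribosome 50S	protein	13.2	0.11
Ribosome 70S	protein	16.6	0.05
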