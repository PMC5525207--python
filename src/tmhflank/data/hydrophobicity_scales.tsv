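# Hydrophobicity scales, one column per scale, one row per residue.
# kyte_doolittle: Kyte & Doolittle (1982) J Mol Biol 157:105 hydropathy index
#   (positive = hydrophobic).
# white_wimley_octanol: Wimley & White whole-residue water->octanol transfer
#   free energy, kcal/mol (positive = polar); charged forms for D/E/K/R/H.
# hessa_biological: Hessa et al. (2005) Nature 433:377 apparent free energy
#   of translocon-mediated membrane insertion, kcal/mol (negative = inserted).
# eisenberg_consensus: Eisenberg et al. (1984) J Mol Biol 179:125 normalized
#   consensus scale (positive = hydrophobic).
residue	kyte_doolittle	white_wimley_octanol	hessa_biological	eisenberg_consensus
A	1.8	0.50	0.11	0.62
C	2.5	-0.02	-0.13	0.29
D	-3.5	3.64	3.49	-0.90
E	-3.5	3.63	2.68	-0.74
F	2.8	-1.71	-0.32	1.19
G	-0.4	1.15	0.74	0.48
H	-3.2	2.33	2.06	-0.40
I	4.5	-1.12	-0.60	1.38
K	-3.9	2.80	2.71	-1.50
L	3.8	-1.25	-0.55	1.06
M	1.9	-0.67	-0.10	0.64
N	-3.5	0.85	2.05	-0.78
P	-1.6	0.14	2.23	0.12
Q	-3.5	0.77	2.36	-0.85
R	-4.5	1.81	2.58	-2.53
S	-0.8	0.46	0.84	-0.18
T	-0.7	0.25	0.52	-0.05
V	4.2	-0.46	-0.31	1.08
W	-0.9	-2.09	0.30	0.81
Y	-1.3	-0.71	0.68	0.26
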