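# HPS-Urry residue parameters for one-bead-per-residue implicit-solvent
# simulations of intrinsically disordered and multidomain proteins.
#
# Provenance:
#   hydropathy: Urry scale, normalised and shifted per the HPS-Urry model
#               (Regy, Thompson, Kim & Mittal, Protein Sci 29:2445, 2020;
#               lambda_i = mu*lambda_Urry,i - Delta with mu=1.0, Delta=0.08).
#   sigma:      van der Waals diameters of the HPS model
#               (Dignon et al., PLoS Comput Biol 14:e1005941, 2018), nm.
#   mass:       average amino-acid residue masses, amu.
#   charge:     integer charges at neutral pH; His neutral (configurable
#               at table-load time, see hpslab.params).
#
# columns: code mass charge sigma hydropathy
code	mass	charge	sigma	hydropathy
A	71.079	0.0	0.504	0.522942
R	156.188	1.0	0.656	0.478824
N	114.104	0.0	0.568	0.508236
D	115.089	-1.0	0.558	0.214119
C	103.139	0.0	0.548	0.567060
Q	128.131	0.0	0.602	0.478824
E	129.116	-1.0	0.592	0.000000
G	57.052	0.0	0.450	0.493530
H	137.141	0.0	0.608	0.684707
I	113.160	0.0	0.618	0.625883
L	113.160	0.0	0.618	0.640589
K	128.174	1.0	0.636	0.302354
M	131.193	0.0	0.618	0.596471
F	147.177	0.0	0.636	0.743530
P	97.117	0.0	0.556	0.678824
S	87.078	0.0	0.518	0.508236
T	101.105	0.0	0.562	0.508236
W	186.213	0.0	0.678	0.920000
Y	163.176	0.0	0.646	0.817059
V	99.133	0.0	0.586	0.584707
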