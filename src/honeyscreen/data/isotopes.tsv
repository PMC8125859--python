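# honeyscreen isotope table v1
# element	isotope_mass_da	abundance_fraction
# IUPAC/CIAAW representative values; lightest isotope listed first per element.
C	12.000000000	0.98930
C	13.003354835	0.01070
H	1.007825032	0.999885
H	2.014101778	0.000115
N	14.003074004	0.99636
N	15.000108899	0.00364
O	15.994914620	0.99757
O	16.999131757	0.00038
O	17.999159613	0.00205
S	31.972071174	0.94990
S	32.971458910	0.00750
S	33.967867012	0.04250
S	35.967080699	0.00010
P	30.973761998	1.00000
Cl	34.968852682	0.75760
Cl	36.965902602	0.24240
Na	22.989769282	1.00000
K	38.963706486	0.932581
K	39.963998166	0.000117
K	40.961825258	0.067302
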