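# Published mitochondrial (ND2) divergences for the Crenadactylus complex (10 candidate taxa): uncorrected pairwise divergence
# statistic: p_uncorrected
label	South-west	Cape Range	Carnarvon	Pilbara	Central Ranges	Kimberley A	Kimberley B	Kimberley C	Kimberley D	Kimberley E
South-west	0.000	0.235	0.183	0.212	0.219	0.256	0.217	0.245	0.239	0.222
Cape Range	0.235	0.000	0.201	0.246	0.254	0.289	0.255	0.264	0.262	0.267
Carnarvon	0.183	0.201	0.000	0.205	0.205	0.243	0.220	0.240	0.232	0.225
Pilbara	0.212	0.246	0.205	0.000	0.171	0.206	0.192	0.209	0.199	0.185
Central Ranges	0.219	0.254	0.205	0.171	0.000	0.203	0.202	0.221	0.217	0.207
Kimberley A	0.256	0.289	0.243	0.206	0.203	0.000	0.191	0.174	0.153	0.153
Kimberley B	0.217	0.255	0.220	0.192	0.202	0.191	0.000	0.181	0.174	0.153
Kimberley C	0.245	0.264	0.240	0.209	0.221	0.174	0.181	0.000	0.161	0.165
Kimberley D	0.239	0.262	0.232	0.199	0.217	0.153	0.174	0.161	0.000	0.139
Kimberley E	0.222	0.267	0.225	0.185	0.207	0.153	0.153	0.165	0.139	0.000
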