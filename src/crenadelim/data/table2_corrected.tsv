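# Published mitochondrial (ND2) divergences for the Crenadactylus complex (10 candidate taxa): model-corrected pairwise divergence
# statistic: corrected
label	South-west	Cape Range	Carnarvon	Pilbara	Central Ranges	Kimberley A	Kimberley B	Kimberley C	Kimberley D	Kimberley E
South-west	0.000	0.623	0.359	0.505	0.512	0.704	0.557	0.657	0.680	0.615
Cape Range	0.623	0.000	0.456	0.709	0.718	1.059	0.872	0.923	0.981	0.997
Carnarvon	0.359	0.456	0.000	0.494	0.457	0.673	0.577	0.698	0.686	0.636
Pilbara	0.505	0.709	0.494	0.000	0.294	0.445	0.421	0.470	0.463	0.405
Central Ranges	0.512	0.718	0.457	0.294	0.000	0.415	0.443	0.491	0.504	0.479
Kimberley A	0.704	1.059	0.673	0.445	0.415	0.000	0.347	0.281	0.221	0.248
Kimberley B	0.557	0.872	0.577	0.421	0.443	0.347	0.000	0.333	0.326	0.281
Kimberley C	0.657	0.923	0.698	0.470	0.491	0.281	0.333	0.000	0.266	0.281
Kimberley D	0.680	0.981	0.686	0.463	0.504	0.221	0.326	0.266	0.000	0.227
Kimberley E	0.615	0.997	0.636	0.405	0.479	0.248	0.281	0.281	0.227	0.000
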