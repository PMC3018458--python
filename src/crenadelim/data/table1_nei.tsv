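# Published allozyme summary for the Crenadactylus complex (10 candidate taxa, 42 loci): Nei's unbiased genetic distance
# statistic: nei_unbiased
label	South-West	Carnarvon Basin	Cape Range	Pilbara	Kimberley A	Kimberley B	Kimberley C	Kimberley D	Kimberley E	Central Ranges
South-West	0.000	0.304	0.355	0.619	0.560	0.657	0.640	0.542	0.623	0.447
Carnarvon Basin	0.304	0.000	0.446	0.794	0.572	0.728	0.810	0.597	0.740	0.531
Cape Range	0.355	0.446	0.000	0.700	0.593	0.557	0.629	0.591	0.607	0.637
Pilbara	0.619	0.794	0.700	0.000	0.439	0.386	0.479	0.491	0.498	0.574
Kimberley A	0.560	0.572	0.593	0.439	0.000	0.194	0.404	0.253	0.314	0.534
Kimberley B	0.657	0.728	0.557	0.386	0.194	0.000	0.368	0.414	0.435	0.593
Kimberley C	0.640	0.810	0.629	0.479	0.404	0.368	0.000	0.321	0.262	0.689
Kimberley D	0.542	0.597	0.591	0.491	0.253	0.414	0.321	0.000	0.120	0.525
Kimberley E	0.623	0.740	0.607	0.498	0.314	0.435	0.262	0.120	0.000	0.575
Central Ranges	0.447	0.531	0.637	0.574	0.534	0.593	0.689	0.525	0.575	0.000
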