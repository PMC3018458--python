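# Published allozyme summary for the Crenadactylus complex (10 candidate taxa, 42 loci): percent fixed differences (10%% cumulative tolerance), as printed (rounded)
# statistic: fd_percent
label	South-West	Carnarvon Basin	Cape Range	Pilbara	Kimberley A	Kimberley B	Kimberley C	Kimberley D	Kimberley E	Central Ranges
South-West	0	24	21	43	44	48	48	39	43	36
Carnarvon Basin	24	0	31	50	44	52	52	41	50	40
Cape Range	21	31	0	48	41	36	43	41	38	40
Pilbara	43	50	48	0	32	31	38	39	38	38
Kimberley A	44	44	41	32	0	17	34	22	24	39
Kimberley B	48	52	36	31	17	0	26	32	29	45
Kimberley C	48	52	43	38	34	26	0	29	19	48
Kimberley D	39	41	41	39	22	32	29	0	10	39
Kimberley E	43	50	38	38	24	29	19	10	0	40
Central Ranges	36	40	40	38	39	45	48	39	40	0
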