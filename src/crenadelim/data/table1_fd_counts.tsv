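# Published allozyme summary for the Crenadactylus complex (10 candidate taxa, 42 loci): fixed-difference counts
# statistic: fd_count
label	South-West	Carnarvon Basin	Cape Range	Pilbara	Kimberley A	Kimberley B	Kimberley C	Kimberley D	Kimberley E	Central Ranges
South-West	0	10	9	18	18	20	20	16	18	15
Carnarvon Basin	10	0	13	21	18	22	22	17	21	17
Cape Range	9	13	0	20	17	15	18	17	16	17
Pilbara	18	21	20	0	13	13	16	16	16	16
Kimberley A	18	18	17	13	0	7	14	9	10	16
Kimberley B	20	22	15	13	7	0	11	13	12	19
Kimberley C	20	22	18	16	14	11	0	12	8	20
Kimberley D	16	17	17	16	9	13	12	0	4	16
Kimberley E	18	21	16	16	10	12	8	4	0	17
Central Ranges	15	17	17	16	16	19	20	16	17	0
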