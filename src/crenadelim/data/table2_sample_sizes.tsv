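# Published mitochondrial (ND2) divergences for the Crenadactylus complex (10 candidate taxa): individuals sequenced per taxon
taxon	n
South-west	7
Cape Range	4
Carnarvon	10
Pilbara	10
Central Ranges	11
Kimberley A	1
Kimberley B	1
Kimberley C	2
Kimberley D	1
Kimberley E	7
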