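# Standard mitochondrial feature table, rCRS coordinates (1-based inclusive).
# Protein ranges are trimmed to whole codons (incomplete stop codons excluded).
# strand: H = heavy (coding as written), L = light (reverse complement).
name	class	strand	start	end
HVS-2	control	H	1	576
tRNA-Phe	tRNA	H	577	647
12S	rRNA	H	648	1601
16S	rRNA	H	1671	3229
ND1	protein	H	3307	4260
ND2	protein	H	4470	5510
CO1	protein	H	5904	7445
CO2	protein	H	7586	8269
ATP8	protein	H	8366	8572
ATP6	protein	H	8527	9207
CO3	protein	H	9207	9989
ND3	protein	H	10059	10403
ND4L	protein	H	10470	10766
ND4	protein	H	10760	12136
ND5	protein	H	12337	14148
ND6	protein	L	14149	14673
CYTB	protein	H	14747	15886
tRNA-Pro	tRNA	L	15956	16023
HVS-1	control	H	16024	16569
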