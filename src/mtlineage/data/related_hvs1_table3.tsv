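# HVS-I haplotypes closely related to, or members of, the mummy's C1b sub-clade.
# Variants are given RELATIVE TO THE C1b ROOT haplotype (the source table's own
# convention); use expand_from_root() to obtain rCRS-relative records.
# The Aymara (La Paz) motif was observed in three individuals and is expanded
# into three records.
sample_id	population	country	period	range	variants
Aconcagua-mummy-CR	Inca	Argentina (Mendoza)	AD 1480	16024-16569	16124
Aymara-Andahuayalas	Aymara	Peru (Apurimac)		16024-16383	16124 16362
PostWari-Huari	Post-Wari	Peru (Ayacucho)	AD 1000-1450	16011-16382	16124 16189 16222 16316
Aymara-LaPaz-1	Aymara	Bolivia (La Paz)		16024-16383	16124 16183C 16189
Aymara-LaPaz-2	Aymara	Bolivia (La Paz)		16024-16383	16124 16183C 16189
Aymara-LaPaz-3	Aymara	Bolivia (La Paz)		16024-16383	16124 16183C 16189
Bolivian-Pucarani	Bolivian	Bolivia (Cochabamba)		16024-16569	16111 16124
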