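# Complete mitogenome haplotype of the Aconcagua Inca child mummy, rCRS-relative.
# Columns: sample_id, population, country, range, variants, private
# "private" lists the variants private within C1b (flagged (P) in the source table).
sample_id	population	country	range	variants	private
Aconcagua-mummy	Inca	Argentina (Mendoza)	1-16569	56T 57 60+T 64 73 249d 263 290-291d 309+C 315+C 455+T 489 493 523-524d 662 750 1438 2563 2706 3552A 4715 4769 5135 7028 7196A 8584 8701 8725 8860 9540 9545 10398 10400 10873 11719 11914 12705 13263 14318 14766 14783 15043 15301 15326 15487T 16124 16223 16298 16325 16327 16519	56T 57 60+T 64 455+T 662 2563 5135 8725 16124
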