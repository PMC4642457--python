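# Synthetic lab-operator haplotypes for the contamination cross-check demo.
# op-H1 is an H1-like European lineage (toy-tree vocabulary); op-C1b2 sits on
# the C1b2 sister clade.  Both are phylogenetically incompatible with a C1b*
# sample carrying its own private branch.
sample_id	population	country	range	variants
op-H1	lab-operator		1-16569	263 750 1438 3010 4769 8860 15326 16519
op-C1b2	lab-operator		1-16569	73 249d 263 290-291d 489 493 750 1438 2706 3552A 4715 4769 7028 7196A 8584 8701 8860 9540 9545 10398 10400 10873 11719 11914 12705 13263 14318 14766 14783 15043 15301 15326 15487T 16051 16223 16292 16298 16325 16327
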