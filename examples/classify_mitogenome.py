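"""Classify a complete mitogenome and extract its private mutations.

Loads the packaged Inca-mummy haplotype (51 rCRS-relative variants), places
it on the packaged haplogroup tree, and lists the variants not explained by
the best clade's defining motif.
"""

from mtlineage import classify_haplotype, load_mummy_haplotype, load_toy_tree

mummy, _ = load_mummy_haplotype()
tree = load_toy_tree()

c = classify_haplotype(mummy, tree)
print(f"sample: {mummy.sample_id}  ({len(mummy.variants)} variants vs rCRS)")
print(f"best haplogroup: {c.best}  (score {c.score}, {len(c.missing)} missing)")
print(f"private mutations ({len(c.private)}):",
      " ".join(str(v) for v in sorted(c.private)))
# The private set is the evidence for a new sub-clade: variants carried by
# the sample but absent from every defining motif on the root path.
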