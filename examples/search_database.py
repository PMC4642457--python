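"""Search a control-region database for members of a haplogroup sub-clade.

Embeds the packaged related-haplotype records (relative to the C1b root, as
published) among 120 synthetic C1b decoys lacking 16124, then searches for
records carrying the C1b HVS-I backbone plus the 16124 transition.
"""

from mtlineage import (
    HaplotypeDB,
    Variant,
    expand_from_root,
    load_related_haplotypes,
    load_toy_tree,
    make_decoy_database,
)

tree = load_toy_tree()
c1b = sorted(tree.cumulative_motif("C1b"))

related = [
    expand_from_root(h, c1b)
    for h in load_related_haplotypes()
    if h.sample_id != "Aconcagua-mummy-CR"
]
db = HaplotypeDB(related + make_decoy_database(120, c1b, seed=0))

hits = db.search_motif(
    required=[Variant(16124)],
    backbone=[v for v in c1b if v.position >= 16024],
)
print(f"database size: {len(db)}; matches: {len(hits)}")
for h in hits:
    print(f"  {h.sample_id:22s} {h.population or '':10s} {h.country or ''}")
# Exactly the six population records match: motif variants outside a
# record's sequenced range are ignored, and the hotspot 16183C is masked,
# so partial-range and hotspot-carrying records are matched correctly.
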