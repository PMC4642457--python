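"""Haplogroup classification, private mutations, nomenclature, subclade
discovery and the contamination cross-check."""

import pytest
from hypothesis import given, settings, strategies as st

from mtlineage import (
    Haplotype,
    HaplogroupTree,
    ReferenceGenome,
    SeqRange,
    Variant,
    classify_haplotype,
    contamination_check,
    discover_subclades,
    load_toy_tree,
    parse_variant,
    private_mutations,
    resolve_nomenclature,
    synthetic_reference,
)
from mtlineage.haplotree import TreeFormatError

from oracles import shared_subset_proposals


def _hap(name, tokens, rng=SeqRange(1, 16569)):
    return Haplotype(name, {parse_variant(t) for t in tokens.split()}, rng)


class TestTreeIO:
    def test_two_line_file(self):
        t = HaplogroupTree.from_text("ROOT\n C1 290-291d 16325\n")
        assert len(t) == 2
        assert {str(v) for v in t.cumulative_motif("C1")} == {"290-291d", "16325"}

    def test_toy_tree_loads(self, toy_tree):
        assert len(toy_tree) >= 6
        for name in ("C1b", "C1b2", "C1b6", "C1b13", "H1", "rCRS"):
            assert name in toy_tree
        assert len(toy_tree.cumulative_motif("C1b")) == 37

    def test_writer_loader_roundtrip(self, toy_tree):
        again = HaplogroupTree.from_text(toy_tree.to_text())
        assert set(again.names()) == set(toy_tree.names())
        for name in toy_tree.names():
            assert again.cumulative_motif(name) == toy_tree.cumulative_motif(name)

    def test_duplicate_name_rejected(self):
        with pytest.raises(TreeFormatError):
            HaplogroupTree.from_text("ROOT\n A 73\n A 93\n")

    def test_orphan_indentation_rejected(self):
        with pytest.raises(TreeFormatError):
            HaplogroupTree.from_text("ROOT\n   A 73\n  B 93\nC 95\nROOT2\n")

    def test_back_mutation_cancels_in_cumulative_motif(self):
        t = HaplogroupTree.from_text("ROOT\n A 73 263\n  B @73 310\n")
        assert {str(v) for v in t.cumulative_motif("B")} == {"263", "310"}

    def test_newick_export_contains_all_names(self, toy_tree):
        nwk = toy_tree.to_newick()
        assert nwk.endswith(";")
        for name in toy_tree.names():
            assert name in nwk


class TestClassification:
    def test_mummy_classifies_to_c1b(self, toy_tree, mummy):
        h, _ = mummy
        c = classify_haplotype(h, toy_tree)
        assert c.best == "C1b"
        assert len(c.missing) == 0
        assert len(c.private) == 10

    def test_exact_motif_classifies_to_node(self, toy_tree):
        for name in ("C1b", "M8", "H1", "C1b13d"):
            h = Haplotype(name + "-exact", toy_tree.cumulative_motif(name))
            c = classify_haplotype(h, toy_tree)
            assert c.best == name
            assert not c.missing and not c.private

    def test_private_variant_does_not_change_best_node(self, toy_tree):
        base = toy_tree.cumulative_motif("C1b")
        h = Haplotype("plus", set(base) | {Variant(5000)})
        c = classify_haplotype(h, toy_tree)
        assert c.best == "C1b"
        assert {str(v) for v in c.private} == {"5000"}

    def test_hvs1_only_classification_ignores_out_of_range_motif(self, toy_tree):
        # C1b HVS-I backbone only, over a control-region range
        tokens = "16223 16298 16325 16327"
        h = _hap("cr", tokens, SeqRange(16024, 16569))
        c = classify_haplotype(h, toy_tree)
        # all coding-region motif variants are ignored (not counted missing);
        # C1b13, whose entire motif is out of range, ties C1b and wins the
        # deterministic greater-depth tie-break
        assert "C1b" in toy_tree.path(c.best)
        assert c.best == "C1b13"
        assert not c.missing

    def test_missing_defining_variant_never_deepens_placement(self, toy_tree):
        full = toy_tree.cumulative_motif("C1b13d")
        h = Haplotype("drop", set(full) - {parse_variant("16104")})
        c = classify_haplotype(h, toy_tree)
        assert c.best == "C1b13"

    def test_empty_tree_raises(self):
        t = HaplogroupTree("ROOT")
        t.nodes.clear()
        with pytest.raises(ValueError):
            classify_haplotype(Haplotype("x"), t)


class TestPrivateMutations:
    def test_mummy_private_set_matches_flagged_rows(self, toy_tree, mummy):
        h, flagged = mummy
        priv = private_mutations(h, "C1b", toy_tree)
        assert priv == flagged
        assert {str(v) for v in priv} == {
            "56T", "57", "60+T", "64", "455+T", "662", "2563", "5135", "8725", "16124"
        }

    def test_exact_motif_has_no_privates(self, toy_tree):
        h = Haplotype("exact", toy_tree.cumulative_motif("C1b"))
        assert private_mutations(h, "C1b", toy_tree) == frozenset()

    def test_missing_motif_variant_not_reported_private(self, toy_tree):
        motif = set(toy_tree.cumulative_motif("C1b"))
        dropped = parse_variant("493")
        h = Haplotype("miss", motif - {dropped})
        priv = private_mutations(h, "C1b", toy_tree)
        assert dropped not in priv and not priv

    def test_unknown_node_raises(self, toy_tree, mummy):
        with pytest.raises(KeyError):
            private_mutations(mummy[0], "nope", toy_tree)


@pytest.fixture(scope="module")
def homopolymer_reference():
    # HVS-II context in which "56T 56+C" and "56T 57 60+T" describe the
    # same molecule: 56=A followed by a T homopolymer at 57-60
    seq = list(synthetic_reference().sequence)
    for pos, b in {55: "G", 56: "A", 57: "T", 58: "T", 59: "T", 60: "T", 61: "G"}.items():
        seq[pos - 1] = b
    return ReferenceGenome("ctx", "".join(seq))


class TestNomenclature:
    def test_phylogeny_preferred_representation_wins(self, homopolymer_reference):
        raw = _hap("amb", "56T 56+C", SeqRange(1, 200))
        tree = HaplogroupTree.from_text("ROOT\n W5 57 60+T\n")
        res = resolve_nomenclature(raw, tree, homopolymer_reference)
        assert {str(v) for v in res.variants} == {"56T", "57", "60+T"}

    def test_resolution_preserves_sample_sequence(self, homopolymer_reference):
        from mtlineage import apply_variants

        raw = _hap("amb", "56T 56+C", SeqRange(1, 200))
        tree = HaplogroupTree.from_text("ROOT\n W5 57 60+T\n")
        res = resolve_nomenclature(raw, tree, homopolymer_reference)
        assert apply_variants(res, homopolymer_reference) == apply_variants(
            raw, homopolymer_reference
        )

    def test_unique_representation_unchanged(self, reference):
        # 455+T sits between pinned non-T neighbours: placement is unique
        raw = _hap("uniq", "455+T 489", SeqRange(1, 600))
        tree = HaplogroupTree.from_text("ROOT\n X 489\n")
        res = resolve_nomenclature(raw, tree, reference)
        assert res.variants == raw.variants

    def test_no_vocabulary_keeps_most_parsimonious_event_count(
        self, homopolymer_reference
    ):
        raw = _hap("amb", "56T 56+C", SeqRange(1, 200))
        tree = HaplogroupTree.from_text("ROOT\n")
        res = resolve_nomenclature(raw, tree, homopolymer_reference)
        assert len(res.variants) == 2  # never worse than the input


class TestSubcladeDiscovery:
    def test_two_sharers_make_one_proposal(self, toy_tree):
        base = toy_tree.cumulative_motif("C1b")
        h1 = Haplotype("a", set(base) | {Variant(16189)})
        h2 = Haplotype("b", set(base) | {Variant(16189)})
        props = discover_subclades([(h1, "C1b"), (h2, "C1b")], toy_tree)
        assert len(props) == 1
        assert {str(v) for v in props[0].motif} == {"16189"}
        assert props[0].members == ("a", "b")

    def test_singleton_variant_makes_no_proposal(self, toy_tree):
        base = toy_tree.cumulative_motif("C1b")
        h1 = Haplotype("a", set(base) | {Variant(16189)})
        h2 = Haplotype("b", set(base))
        assert discover_subclades([(h1, "C1b"), (h2, "C1b")], toy_tree) == []

    def test_planted_nesting_matches_brute_force(self, toy_tree):
        base = toy_tree.cumulative_motif("C1b")
        A, B = Variant(5000), Variant(6000)
        haps = [Haplotype(f"a{i}", set(base) | {A}) for i in range(3)]
        haps += [Haplotype(f"b{i}", set(base) | {A, B}) for i in range(2)]
        haps += [Haplotype("c", set(base))]
        props = discover_subclades([(h, "C1b") for h in haps], toy_tree)
        got = {(frozenset(p.motif), frozenset(p.members)) for p in props}
        priv = {h.sample_id: set(private_mutations(h, "C1b", toy_tree)) for h in haps}
        assert got == shared_subset_proposals(priv)
        nested = [p for p in props if p.nested_under]
        assert len(nested) == 1 and set(nested[0].members) == {"b0", "b1"}

    @given(data=st.data())
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_random_instances_match_brute_force(self, data):
        tree = load_toy_tree()
        base = tree.cumulative_motif("C1b")
        pool = [Variant(p) for p in (5000, 6000, 7000, 7500, 12000, 13000)]
        n = data.draw(st.integers(2, 8))
        haps = []
        for i in range(n):
            extra = data.draw(st.sets(st.sampled_from(pool), max_size=4), label=f"h{i}")
            haps.append(Haplotype(f"s{i}", set(base) | set(extra)))
        props = discover_subclades([(h, "C1b") for h in haps], tree)
        got = {(frozenset(p.motif), frozenset(p.members)) for p in props}
        priv = {h.sample_id: set(private_mutations(h, "C1b", tree)) for h in haps}
        assert got == shared_subset_proposals(priv)

    def test_min_members_below_two_rejected(self, toy_tree):
        with pytest.raises(ValueError):
            discover_subclades([], toy_tree, min_members=1)


class TestContamination:
    def test_h_lineage_operator_incompatible_with_c1b_sample(self, toy_tree, mummy):
        from mtlineage import load_operator_haplotypes

        sample, _ = mummy
        reports = contamination_check(sample, load_operator_haplotypes(), toy_tree)
        by_id = {r.operator_id: r for r in reports}
        assert by_id["op-H1"].best_node == "H1"
        assert by_id["op-H1"].verdict == "incompatible"

    def test_sister_clade_operator_incompatible(self, toy_tree, mummy):
        from mtlineage import load_operator_haplotypes

        sample, _ = mummy
        reports = contamination_check(sample, load_operator_haplotypes(), toy_tree)
        by_id = {r.operator_id: r for r in reports}
        assert by_id["op-C1b2"].best_node == "C1b2"
        assert by_id["op-C1b2"].verdict == "incompatible"

    def test_identical_operator_flagged_for_review(self, toy_tree, mummy):
        sample, _ = mummy
        twin = Haplotype("twin", sample.variants, sample.range)
        (report,) = contamination_check(sample, [twin], toy_tree)
        assert report.verdict == "compatible (identical, review)"

    def test_empty_operator_set_raises(self, toy_tree, mummy):
        with pytest.raises(ValueError):
            contamination_check(mummy[0], [], toy_tree)
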