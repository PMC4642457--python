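"""Within-clade maximum-parsimony genealogies.

mtDNA clades are near-perfect phylogenies, so the builder uses greedy
agglomeration of shared derived variants (most widely shared first, ties by
position), which attains the minimum tree length whenever the characters
are pairwise compatible and labels recurrences when they are not.  The
exhaustive-search oracle used in the test suite lives with the tests, not
here.

Branches carry mutation lists; a branch's length is its event count.  Tips
carry sample ids and multiplicity (identical haplotypes merge).  The two
quantities downstream dating consumes are the per-tip root distances d_i
and the per-branch (length l_b, descendant tip count n_b) pairs, linked by
the identity sum_b l_b*n_b = sum_i d_i.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .variants import (
    DATING_MASK,
    Haplotype,
    HotspotMask,
    Variant,
    mask_hotspots,
)
from .sequences import SYNONYMOUS, GeneMap, ReferenceGenome, annotate_variant


@dataclass
class GNode:
    node_id: int
    parent: Optional[int]
    branch_mutations: Tuple[Variant, ...]  # on the edge above this node
    children: List[int] = field(default_factory=list)
    sample_ids: Tuple[str, ...] = ()       # nonempty iff a sampled haplotype sits here

    @property
    def multiplicity(self) -> int:
        return len(self.sample_ids)


class GenealogyTree:
    """Rooted genealogy with mutation-labelled branches."""

    def __init__(self):
        self.nodes: Dict[int, GNode] = {0: GNode(0, None, ())}
        self._next = 1

    @property
    def root(self) -> GNode:
        return self.nodes[0]

    def add_node(self, parent: int, mutations: Sequence[Variant],
                 sample_ids: Sequence[str] = ()) -> int:
        nid = self._next
        self._next += 1
        self.nodes[nid] = GNode(nid, parent, tuple(mutations), sample_ids=tuple(sample_ids))
        self.nodes[parent].children.append(nid)
        return nid

    def tips(self) -> List[GNode]:
        return [n for n in self.nodes.values() if n.sample_ids]

    @property
    def n(self) -> int:
        """Total sampled mtDNAs (tips weighted by multiplicity)."""
        return sum(n.multiplicity for n in self.tips())

    def total_length(self, event_filter: str = "all", **ann) -> int:
        return sum(
            len(self._filtered(n.branch_mutations, event_filter, **ann))
            for n in self.nodes.values()
            if n.parent is not None
        )

    def _filtered(self, muts: Tuple[Variant, ...], event_filter: str,
                  gene_map: Optional[GeneMap] = None,
                  reference: Optional[ReferenceGenome] = None) -> List[Variant]:
        if event_filter == "all":
            return list(muts)
        if event_filter != "synonymous":
            raise ValueError(f"unknown event filter {event_filter!r}")
        if gene_map is None or reference is None:
            raise ValueError("synonymous-only filtering requires gene_map and reference")
        keep = []
        for v in muts:
            base = replace(v, back_mutation=False)
            if base.is_indel:
                continue
            if annotate_variant(base, gene_map, reference).effect == SYNONYMOUS:
                keep.append(v)
        return keep

    def root_distances(self, event_filter: str = "all",
                       gene_map: Optional[GeneMap] = None,
                       reference: Optional[ReferenceGenome] = None) -> List[Tuple[str, int]]:
        """Per-sample (id, mutations-to-root); one entry per sampled mtDNA."""
        out = []
        for tip in self.tips():
            d = 0
            node = tip
            while node.parent is not None:
                d += len(self._filtered(node.branch_mutations, event_filter,
                                        gene_map=gene_map, reference=reference))
                node = self.nodes[node.parent]
            for sid in tip.sample_ids:
                out.append((sid, d))
        return sorted(out)

    def branch_weights(self, event_filter: str = "all",
                       gene_map: Optional[GeneMap] = None,
                       reference: Optional[ReferenceGenome] = None) -> List[Tuple[int, int, int]]:
        """Per-branch (child node id, length l_b, descendant tips n_b)."""
        # descendant multiplicities via postorder accumulation
        desc: Dict[int, int] = {nid: n.multiplicity for nid, n in self.nodes.items()}
        order = self._postorder()
        for nid in order:
            node = self.nodes[nid]
            if node.parent is not None:
                desc[node.parent] = desc.get(node.parent, 0) + desc[nid]
        out = []
        for nid in sorted(self.nodes):
            node = self.nodes[nid]
            if node.parent is None:
                continue
            l_b = len(self._filtered(node.branch_mutations, event_filter,
                                     gene_map=gene_map, reference=reference))
            out.append((nid, l_b, desc[nid]))
        return out

    def _postorder(self) -> List[int]:
        out, stack = [], [0]
        while stack:
            nid = stack.pop()
            out.append(nid)
            stack.extend(self.nodes[nid].children)
        return out[::-1]

    def to_newick(self) -> str:
        """Newick with branch lengths = mutation counts and mutation lists
        as bracketed comments."""

        def label(node: GNode) -> str:
            name = "|".join(node.sample_ids) if node.sample_ids else ""
            muts = " ".join(str(v) for v in node.branch_mutations)
            comment = f"[&mutations={muts}]" if muts else ""
            length = f":{len(node.branch_mutations)}" if node.parent is not None else ""
            return f"{name}{comment}{length}"

        def emit(nid: int) -> str:
            node = self.nodes[nid]
            if not node.children:
                return label(node)
            inner = ",".join(emit(c) for c in node.children)
            return f"({inner}){label(node)}"

        return emit(0) + ";"


def build_parsimony_tree(
    haplotypes: Iterable[Haplotype],
    root: Haplotype,
    mask: HotspotMask = DATING_MASK,
    count_indels: bool = False,
) -> GenealogyTree:
    """Greedy maximum-parsimony genealogy of haplotypes below a clade root.

    Derived states are computed against the (masked) root haplotype; a root
    variant absent from a sample becomes a back mutation.  Identical
    haplotypes merge into one tip with multiplicity.
    """
    haplotypes = list(haplotypes)
    if not haplotypes:
        raise ValueError("empty input")
    root_m = mask_hotspots(root, mask)

    def derived(h: Haplotype) -> frozenset:
        hm = mask_hotspots(h, mask)
        plus = hm.variants - root_m.variants
        minus = {replace(v, back_mutation=True) for v in root_m.variants - hm.variants
                 if hm.range.contains_variant(v)}
        both = plus | minus
        if not count_indels:
            both = {v for v in both if not v.is_indel}
        return frozenset(both)

    groups: Dict[frozenset, List[str]] = {}
    for h in haplotypes:
        groups.setdefault(derived(h), []).append(h.sample_id)
    items = [(sorted(ids), vs) for vs, ids in groups.items()]
    items.sort(key=lambda t: t[0][0])

    tree = GenealogyTree()
    _grow(tree, 0, items)
    return tree


def _grow(tree: GenealogyTree, parent: int, items: List[Tuple[List[str], frozenset]]) -> None:
    pool = list(items)
    # samples identical to the parent's state become zero-length tips
    for ids, vs in [it for it in pool if not it[1]]:
        tree.add_node(parent, (), sample_ids=ids)
    pool = [it for it in pool if it[1]]
    while pool:
        if len(pool) == 1:
            ids, vs = pool.pop()
            tree.add_node(parent, sorted(vs), sample_ids=ids)
            continue
        counts: Dict[Variant, int] = {}
        for _, vs in pool:
            for v in vs:
                counts[v] = counts.get(v, 0) + 1
        v_star = min(counts, key=lambda v: (-counts[v], v.position, str(v)))
        carriers = [it for it in pool if v_star in it[1]]
        rest = [it for it in pool if v_star not in it[1]]
        if len(carriers) == 1:
            ids, vs = carriers[0]
            tree.add_node(parent, sorted(vs), sample_ids=ids)
            pool = rest
            continue
        shared = frozenset.intersection(*[vs for _, vs in carriers])
        child = tree.add_node(parent, sorted(shared))
        _grow(tree, child, [(ids, vs - shared) for ids, vs in carriers])
        pool = rest


def direct_root_distances(
    haplotypes: Iterable[Haplotype],
    root: Haplotype,
    mask: HotspotMask = DATING_MASK,
    count_indels: bool = False,
) -> List[Tuple[str, int]]:
    """Haplotype-vs-root mutation counts without building a genealogy.

    Identical to tree-based root distances on star-like data; exposed
    because published rho values are sometimes computed either way.
    """
    from .variants import mutational_distance

    return sorted(
        (h.sample_id, mutational_distance(h, root, count_indels=count_indels, mask=mask))
        for h in haplotypes
    )
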