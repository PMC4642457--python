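"""Haplogroup trees: classification, private mutations, nomenclature,
subclade discovery and contamination cross-checks.

The tree file format is plain text, one node per line, hierarchy by leading
indentation: ``name  token token ...`` where tokens are compact variant
notation (back mutations allowed with ``@``).  A node's *cumulative motif*
is the concatenation of edge motifs from the root, with a back mutation
cancelling the corresponding earlier variant.

Classification scores a haplotype against every node as
(#matched defining variants) − (#missing defining variants within the
sample's sequenced range); motif variants outside the sequenced range are
ignored, which permits control-region-only classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .variants import (
    DEFAULT_MASK,
    Haplotype,
    HotspotMask,
    Variant,
    format_variant,
    mask_hotspots,
    parse_variant,
)
from .sequences import ReferenceGenome, apply_variants, _small_alignment


class TreeFormatError(ValueError):
    pass


@dataclass
class TreeNode:
    name: str
    motif: Tuple[Variant, ...] = ()
    parent: Optional[str] = None
    children: List[str] = field(default_factory=list)


class HaplogroupTree:
    """Rooted named-clade tree with edge motifs."""

    def __init__(self, root: str = "ROOT"):
        self.root = root
        self.nodes: Dict[str, TreeNode] = {root: TreeNode(root)}
        self._cumulative: Dict[str, frozenset] = {}

    def add_node(self, name: str, parent: str, motif: Sequence[Variant] = ()) -> None:
        if not name:
            raise TreeFormatError("empty node name")
        if name in self.nodes:
            raise TreeFormatError(f"duplicate node name {name!r}")
        if parent not in self.nodes:
            raise TreeFormatError(f"unknown parent {parent!r} for node {name!r}")
        self.nodes[name] = TreeNode(name, tuple(motif), parent)
        self.nodes[parent].children.append(name)
        self._cumulative.clear()

    def __contains__(self, name: str) -> bool:
        return name in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def names(self) -> List[str]:
        return list(self.nodes)

    def path(self, name: str) -> List[str]:
        """Root-to-node list of node names."""
        if name not in self.nodes:
            raise KeyError(f"unknown node {name!r}")
        out = []
        cur: Optional[str] = name
        while cur is not None:
            out.append(cur)
            cur = self.nodes[cur].parent
        return out[::-1]

    def depth(self, name: str) -> int:
        return len(self.path(name)) - 1

    def cumulative_motif(self, name: str) -> frozenset:
        """Root-to-node motif with back mutations cancelling.

        A back mutation whose target was never gained along the path is
        dropped (it encodes the reference state, which is the default).
        """
        if name in self._cumulative:
            return self._cumulative[name]
        state: Set[Variant] = set()
        for node_name in self.path(name):
            for v in self.nodes[node_name].motif:
                if v.back_mutation:
                    state.discard(replace(v, back_mutation=False))
                else:
                    state.add(v)
        result = frozenset(state)
        self._cumulative[name] = result
        return result

    def motif_vocabulary(self) -> frozenset:
        vocab: Set[Variant] = set()
        for node in self.nodes.values():
            for v in node.motif:
                vocab.add(replace(v, back_mutation=False))
        return frozenset(vocab)

    def deepest_common_ancestor(self, a: str, b: str) -> str:
        pa, pb = self.path(a), self.path(b)
        dca = self.root
        for x, y in zip(pa, pb):
            if x != y:
                break
            dca = x
        return dca

    # -- serialisation ----------------------------------------------------

    def to_text(self) -> str:
        lines: List[str] = []

        def emit(name: str, depth: int):
            node = self.nodes[name]
            tokens = " ".join(format_variant(v) for v in node.motif)
            lines.append(" " * depth + name + ((" " + tokens) if tokens else ""))
            for child in node.children:
                emit(child, depth + 1)

        emit(self.root, 0)
        return "\n".join(lines) + "\n"

    def to_newick(self) -> str:
        def emit(name: str) -> str:
            node = self.nodes[name]
            if not node.children:
                return name
            return "(" + ",".join(emit(c) for c in node.children) + ")" + name

        return emit(self.root) + ";"

    @classmethod
    def from_text(cls, text: str) -> "HaplogroupTree":
        tree: Optional[HaplogroupTree] = None
        stack: List[Tuple[int, str]] = []  # (indent, name)
        for lineno, raw in enumerate(text.splitlines(), 1):
            if not raw.strip() or raw.lstrip().startswith("#"):
                continue
            indent = len(raw) - len(raw.lstrip(" "))
            parts = raw.strip().split()
            name, tokens = parts[0], parts[1:]
            motif = tuple(parse_variant(t) for t in tokens)
            if tree is None:
                if indent != 0:
                    raise TreeFormatError(f"line {lineno}: root must not be indented")
                tree = cls(root=name)
                tree.nodes[name].motif = motif
                stack = [(0, name)]
                continue
            while stack and stack[-1][0] >= indent:
                stack.pop()
            if not stack:
                raise TreeFormatError(f"line {lineno}: orphan indentation for {name!r}")
            tree.add_node(name, parent=stack[-1][1], motif=motif)
            stack.append((indent, name))
        if tree is None:
            raise TreeFormatError("empty tree file")
        return tree


def load_tree(path) -> HaplogroupTree:
    with open(path) as fh:
        return HaplogroupTree.from_text(fh.read())


def write_tree(tree: HaplogroupTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_text())


def load_toy_tree() -> HaplogroupTree:
    from .io import packaged_tree_text

    return HaplogroupTree.from_text(packaged_tree_text())


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Classification:
    best: str
    score: int
    matched: frozenset
    missing: frozenset
    private: frozenset
    runners_up: tuple  # ((name, score), ...) sorted by rank


def _score_node(h_masked: Haplotype, motif: frozenset) -> Tuple[int, frozenset, frozenset]:
    in_range = {v for v in motif if h_masked.range.contains_variant(v)}
    matched = frozenset(in_range & h_masked.variants)
    missing = frozenset(in_range - h_masked.variants)
    return len(matched) - len(missing), matched, missing


def classify_haplotype(
    h: Haplotype,
    tree: HaplogroupTree,
    mask: HotspotMask = DEFAULT_MASK,
) -> Classification:
    """Best-scoring haplogroup assignment; deterministic tie-breaking
    (greater depth, then lexicographic name)."""
    if len(tree) == 0:
        raise ValueError("empty tree")
    hm = mask_hotspots(h, mask)
    scored = []
    for name in tree.names():
        score, matched, missing = _score_node(hm, tree.cumulative_motif(name))
        scored.append((score, tree.depth(name), name, matched, missing))
    scored.sort(key=lambda t: (-t[0], -t[1], t[2]))
    best_score, _, best_name, matched, missing = scored[0]
    private = frozenset(hm.variants - tree.cumulative_motif(best_name))
    runners = tuple((name, score) for score, _, name, _, _ in scored[1:6])
    return Classification(best_name, best_score, matched, missing, private, runners)


def private_mutations(
    h: Haplotype,
    node: str,
    tree: HaplogroupTree,
    mask: HotspotMask = DEFAULT_MASK,
) -> frozenset:
    """Masked variants of ``h`` not in the node's cumulative motif."""
    if node not in tree:
        raise KeyError(f"unknown node {node!r}")
    hm = mask_hotspots(h, mask)
    return frozenset(hm.variants - tree.cumulative_motif(node))


# ---------------------------------------------------------------------------
# Phylogeny-aware nomenclature
# ---------------------------------------------------------------------------

def resolve_nomenclature(
    h: Haplotype,
    tree: HaplogroupTree,
    reference: ReferenceGenome,
    window: int = 8,
    slack: int = 1,
) -> Haplotype:
    """Choose among alignment-equivalent variant representations.

    For each region of the haplotype containing indels, the sample sequence
    is reconstructed and every representation within ``slack`` events of the
    most parsimonious one is enumerated; the representation maximising the
    number of variants found in the tree's motif vocabulary wins, ties
    broken by fewer events, then leftmost placement.  Representations are
    alignment-equivalent: they all reconstruct the same sample sequence.
    """
    indels = sorted(v for v in h.variants if v.is_indel and not v.back_mutation)
    if not indels:
        return h
    vocab = tree.motif_vocabulary()
    # group indels into windows, merging overlaps
    regions: List[Tuple[int, int]] = []
    for v in indels:
        lo, hi = v.position - window, v.end_position + window
        if regions and lo <= regions[-1][1]:
            regions[-1] = (regions[-1][0], max(regions[-1][1], hi))
        else:
            regions.append((lo, hi))
    chosen: Set[Variant] = set(v for v in h.variants)
    for lo, hi in regions:
        lo = max(lo, 1)
        hi = min(hi, reference.length)
        local = {v for v in h.variants
                 if lo <= v.position and v.end_position <= hi and not v.back_mutation}
        sub = Haplotype(h.sample_id, frozenset(local), h.range.__class__(lo, hi))
        sample_window = apply_variants(sub, reference)
        ref_window = reference.segment(sub.range)
        reps = _enumerate_representations(ref_window, sample_window, lo, slack)
        if not reps:
            continue

        def rank(rep: frozenset):
            hits = sum(1 for v in rep if replace(v, back_mutation=False) in vocab)
            placement = tuple(sorted((v.position, str(v)) for v in rep))
            return (-hits, len(rep), placement)

        best = min(reps, key=rank)
        chosen -= local
        chosen |= set(best)
    return h.with_variants(chosen)


def _enumerate_representations(ref: str, alt: str, start_pos: int, slack: int) -> List[frozenset]:
    """All variant-set representations of ref->alt within ``slack`` extra
    events' cost of the minimum (per-base alignment costs, as in calling);
    positions offset by ``start_pos``."""
    SUB, GAP, OPEN = 100, 100, 1
    base_ops = _small_alignment(ref, alt)
    min_cost = 0
    for kind, i, j, bases in base_ops:
        if kind == "sub":
            min_cost += SUB
        elif kind == "del":
            min_cost += OPEN + GAP * (j - i + 1)
        else:
            min_cost += OPEN + GAP * len(bases)
    budget = min_cost + slack * (SUB + OPEN + 4)
    results: List[frozenset] = []
    seen: Set[frozenset] = set()

    def rec(i: int, j: int, events: List[Tuple[str, int, int, str]], cost: int,
            last_op: str):
        if cost > budget:
            return
        if i == len(ref) and j == len(alt):
            rep = _events_to_variants(events, ref, start_pos)
            if rep is not None and rep not in seen:
                seen.add(rep)
                results.append(rep)
            return
        if i < len(ref) and j < len(alt):
            if ref[i] == alt[j]:
                rec(i + 1, j + 1, events, cost, "match")
            else:
                events.append(("sub", i, i, alt[j]))
                rec(i + 1, j + 1, events, cost + SUB, "sub")
                events.pop()
        if i < len(ref):
            if last_op == "del" and events and events[-1][2] == i - 1:
                old = events[-1]
                events[-1] = ("del", old[1], i, "")
                rec(i + 1, j, events, cost + GAP, "del")
                events[-1] = old
            events.append(("del", i, i, ""))
            rec(i + 1, j, events, cost + OPEN + GAP, "del")
            events.pop()
        if j < len(alt):
            if last_op == "ins" and events:
                old = events[-1]
                events[-1] = ("ins", old[1], old[2], old[3] + alt[j])
                rec(i, j + 1, events, cost + GAP, "ins")
                events[-1] = old
            events.append(("ins", i - 1, i - 1, alt[j]))
            rec(i, j + 1, events, cost + OPEN + GAP, "ins")
            events.pop()

    rec(0, 0, [], 0, "start")
    return results


def _events_to_variants(events, ref: str, start_pos: int) -> Optional[frozenset]:
    from .sequences import _substitution

    out = []
    for kind, i, j, bases in events:
        if kind == "sub":
            out.append(_substitution(start_pos + i, ref[i], bases))
        elif kind == "del":
            out.append(Variant(start_pos + i, "deletion", end_position=start_pos + j))
        else:
            if i < 0:
                return None  # insertion before the window start is not representable
            out.append(Variant(start_pos + i, "insertion", derived_allele=bases))
    keys = [v.key for v in out]
    if len(keys) != len(set(keys)):
        return None
    return frozenset(out)


# ---------------------------------------------------------------------------
# Subclade discovery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubcladeProposal:
    parent: str
    motif: tuple          # full private motif (sorted variants, relative to parent node)
    members: tuple        # sample ids
    nested_under: Optional[tuple] = None  # motif of the enclosing proposal, if any

    @property
    def name(self) -> str:
        return f"{self.parent}+" + ",".join(str(v) for v in self.motif)


def discover_subclades(
    placed: Iterable[Tuple[Haplotype, str]],
    tree: HaplogroupTree,
    min_members: int = 2,
    mask: HotspotMask = DEFAULT_MASK,
) -> List[SubcladeProposal]:
    """Propose new named sub-clades from shared private variation.

    For each node, every *closed* set of private variants shared by at least
    ``min_members`` haplotypes becomes a proposal; nested sharing yields
    nested proposals.  Exact closed-itemset enumeration, so the result
    matches brute-force enumeration of shared subsets.
    """
    if min_members < 2:
        raise ValueError("min_members must be >= 2")
    by_node: Dict[str, List[Tuple[str, frozenset]]] = {}
    for h, node in placed:
        priv = private_mutations(h, node, tree, mask)
        by_node.setdefault(node, []).append((h.sample_id, priv))

    proposals: List[SubcladeProposal] = []
    for node in sorted(by_node):
        members = by_node[node]
        carrier: Dict[Variant, frozenset] = {}
        for sid, priv in members:
            for v in priv:
                carrier[v] = carrier.get(v, frozenset()) | {sid}
        # intersection-closure of carrier sets
        sets = {c for c in carrier.values() if len(c) >= min_members}
        closed = set(sets)
        frontier = set(sets)
        while frontier:
            new = set()
            for a in frontier:
                for b in sets:
                    c = a & b
                    if len(c) >= min_members and c not in closed:
                        new.add(c)
            closed |= new
            frontier = new
        items = []
        for c in closed:
            motif = frozenset(v for v, cv in carrier.items() if c <= cv)
            if motif:
                items.append((motif, c))
        # dedupe by motif (keep the largest carrier set = the closure)
        best: Dict[frozenset, frozenset] = {}
        for motif, c in items:
            if motif not in best or len(c) > len(best[motif]):
                best[motif] = c
        for motif in sorted(best, key=lambda m: (min(v.position for v in m), len(m))):
            c = best[motif]
            supersets = [m for m in best if m < motif]
            enclosing = max(supersets, key=len) if supersets else None
            proposals.append(
                SubcladeProposal(
                    parent=node,
                    motif=tuple(sorted(motif)),
                    members=tuple(sorted(c)),
                    nested_under=tuple(sorted(enclosing)) if enclosing else None,
                )
            )
    return proposals


# ---------------------------------------------------------------------------
# Contamination cross-check
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OperatorReport:
    operator_id: str
    best_node: str
    shared_variants: int
    verdict: str  # "incompatible" | "compatible" | "compatible (identical, review)"


def contamination_check(
    sample: Haplotype,
    operators: Iterable[Haplotype],
    tree: HaplogroupTree,
    mask: HotspotMask = DEFAULT_MASK,
) -> List[OperatorReport]:
    """Phylogenetic compatibility of lab-operator haplotypes with a sample.

    Each haplotype is placed on the tree; its effective lineage is the root
    path of its best node, extended by a virtual private branch when private
    mutations are present.  Two lineages are compatible only when one
    effective path is a prefix of the other; divergence below the deepest
    common ancestor is reported as "incompatible".
    """
    operators = list(operators)
    if not operators:
        raise ValueError("empty operator set")
    cs = classify_haplotype(sample, tree, mask)
    sm = mask_hotspots(sample, mask)
    sample_path = _effective_path(tree, cs)
    reports = []
    for op in operators:
        co = classify_haplotype(op, tree, mask)
        om = mask_hotspots(op, mask)
        shared = len({v for v in (sm.variants & om.variants)
                      if om.range.contains_variant(v) and sm.range.contains_variant(v)})
        op_path = _effective_path(tree, co)
        if op_path == sample_path:
            verdict = "compatible (identical, review)"
        elif _is_prefix(op_path, sample_path) or _is_prefix(sample_path, op_path):
            verdict = "compatible"
        else:
            verdict = "incompatible"
        reports.append(OperatorReport(op.sample_id, co.best, shared, verdict))
    return reports


def _effective_path(tree: HaplogroupTree, c: Classification) -> tuple:
    path = tuple(tree.path(c.best))
    if c.private:
        path = path + (("*private*",) + tuple(sorted(str(v) for v in c.private)),)
    return path


def _is_prefix(a: tuple, b: tuple) -> bool:
    return len(a) <= len(b) and b[: len(a)] == a
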