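"""Independent brute-force oracles used by the test suite.

The parsimony oracle enumerates every rooted binary genealogy over the
distinct input haplotypes (root haplotype fixed ancestral) and scores each
with the Fitch algorithm on binary presence/absence characters, returning
the exact minimum total number of state changes.  It shares no code with
the package's greedy tree builder.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import combinations


@lru_cache(maxsize=None)
def rooted_topologies(k: int):
    """All rooted binary tree shapes over leaves 0..k-1 as nested tuples."""
    if k == 1:
        return (0,)
    trees = [0]
    for leaf in range(1, k):
        trees = [t2 for t in trees for t2 in _insert_leaf(t, leaf)]
    return tuple(trees)


def _insert_leaf(tree, leaf):
    out = [(tree, leaf)]
    if isinstance(tree, tuple):
        a, b = tree
        out.extend((t2, b) for t2 in _insert_leaf(a, leaf))
        out.extend((a, t2) for t2 in _insert_leaf(b, leaf))
    return out


def min_parsimony_length(haplotype_sets, root_set=frozenset()) -> int:
    """Exact minimum-parsimony length for haplotypes given as variant sets.

    Characters are binary (variant present/absent); the genealogy root is
    fixed at ``root_set`` (ancestral states).  Distinct haplotypes only:
    duplicates do not change tree length.
    """
    sets = [frozenset(s) for s in haplotype_sets]
    distinct = sorted(set(sets) - {frozenset(root_set)}, key=sorted)
    if not distinct:
        return 0
    sites = sorted({v for s in distinct for v in s} | set(root_set))
    n_sites = len(sites)
    # 2 bits per site: 0b01 = ancestral-state member, 0b10 = derived
    leaf_codes = []
    for s in distinct:
        code = 0
        for i, site in enumerate(sites):
            bit = 0b10 if site in s else 0b01
            code |= bit << (2 * i)
        leaf_codes.append(code)
    root_code = 0
    for i, site in enumerate(sites):
        bit = 0b10 if site in root_set else 0b01
        root_code |= bit << (2 * i)

    odd_mask = int("01" * n_sites, 2)

    def fitch(node):
        """Return (state-set code, changes)."""
        if isinstance(node, int):
            return leaf_codes[node], 0
        (ca, na), (cb, nb) = fitch(node[0]), fitch(node[1])
        inter = ca & cb
        # per-site pair: occupied iff either bit set
        occupied = (inter | (inter >> 1)) & odd_mask
        empty = (~occupied) & odd_mask
        changes = na + nb + bin(empty).count("1")
        union = ca | cb
        result = inter | (union & (empty | (empty << 1)))
        return result, changes

    best = None
    for topo in rooted_topologies(len(distinct)):
        code, changes = fitch(topo)
        # connect to the fixed-state root leaf
        inter = code & root_code
        occupied = (inter | (inter >> 1)) & odd_mask
        extra = n_sites - bin(occupied).count("1")
        total = changes + extra
        if best is None or total < best:
            best = total
    return best


def shared_subset_proposals(private_sets, min_members=2):
    """Brute-force closed shared-variant subsets with >= min_members carriers.

    ``private_sets``: {sample_id: set of variants}.  Returns a set of
    (frozenset motif, frozenset carriers) pairs, where each motif is the
    full set of variants common to its carrier group and each carrier group
    is the full set of samples containing the motif (closed itemsets).
    """
    ids = sorted(private_sets)
    out = set()
    for r in range(min_members, len(ids) + 1):
        for group in combinations(ids, r):
            motif = frozenset.intersection(*[frozenset(private_sets[g]) for g in group])
            if not motif:
                continue
            carriers = frozenset(i for i in ids if motif <= set(private_sets[i]))
            if len(carriers) >= min_members:
                out.add((motif, carriers))
    return out
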