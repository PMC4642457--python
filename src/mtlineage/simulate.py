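"""Synthetic-data generators with the statistical structure rho dating assumes.

Mutations accumulate along genealogy branches as a Poisson process at the
clock rate (infinite-sites by default, so every event hits a fresh site and
within-clade data form a perfect phylogeny, the regime real mtDNA clades
approximate).  Positions are drawn per functional class: clocks counting
synonymous substitutions place their events on sites where a transition is
synonymous, and replacement-site "decoration" mutations are added so the
synonymous fraction of coding mutations matches the requested value.

All randomness flows from the spec seed, so equal seeds give byte-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .dating import (
    ClockSpec,
    SYNONYMOUS_CLOCK,
    compute_rho,
    compute_sigma,
    interval_years,
    rho_to_years,
)
from .parsimony import build_parsimony_tree
from .sequences import (
    GeneMap,
    ReferenceGenome,
    load_gene_map,
    replacement_transition_sites,
    synonymous_transition_sites,
    synthetic_reference,
)
from .variants import (
    DATING_MASK,
    FULL_RANGE,
    Haplotype,
    HotspotMask,
    SeqRange,
    Variant,
)


@dataclass(frozen=True)
class SimulationSpec:
    """Conditions for one simulated clade."""

    n: int
    tmrca_years: float
    clock: ClockSpec = SYNONYMOUS_CLOCK
    topology: str = "star"             # "star" | "yule"
    synonymous_fraction: float = 0.55  # of coding mutations (decoration rate)
    allow_recurrence: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n < 1 or self.tmrca_years < 0:
            raise ValueError("n must be >= 1 and TMRCA non-negative")
        if self.topology not in ("star", "yule"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if not 0 < self.synonymous_fraction <= 1:
            raise ValueError("synonymous_fraction must lie in (0, 1]")


@dataclass
class SimulatedClade:
    haplotypes: List[Haplotype]
    root: Haplotype
    true_tmrca_years: float
    true_genealogy: List[Tuple[str, float]]  # (sample_id, branch-years to root)


class _SitePools:
    """Cached per-(reference, gene map) mutable site pools."""

    _cache: Dict[int, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    @classmethod
    def get(cls, reference: ReferenceGenome, gene_map: GeneMap,
            mask: HotspotMask) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        key = id(gene_map) ^ hash(reference.sequence[:64]) ^ hash(reference.length)
        if key not in cls._cache:
            syn = synonymous_transition_sites(gene_map, reference)
            rep = replacement_transition_sites(gene_map, reference)
            coding = set(syn) | set(rep)
            allpos = np.array(
                [p for p in range(1, reference.length + 1)
                 if not mask.matches(Variant(p)) and p not in coding],
                dtype=int,
            )
            cls._cache[key] = (syn, rep, allpos)
        return cls._cache[key]


def _branch_years(spec: SimulationSpec, rng: np.random.Generator) -> List[List[float]]:
    """Per-tip list of branch lengths (years) root->tip; shared internal
    branches are represented by shared prefixes via a tree walk."""
    if spec.topology == "star" or spec.n == 1:
        return [[spec.tmrca_years] for _ in range(spec.n)]
    # Yule-like: random coalescent-free bifurcation, depths scaled to TMRCA
    # build a random rooted binary tree by sequential random attachment
    children: Dict[int, List[int]] = {0: []}
    next_id = 1
    leaves = [0]
    while len(leaves) < spec.n:
        pick = int(rng.integers(len(leaves)))
        leaf = leaves.pop(pick)
        a, b = next_id, next_id + 1
        next_id += 2
        children[leaf] = [a, b]
        children[a] = []
        children[b] = []
        leaves.extend([a, b])
    # assign internal node depths increasing from root, ultrametric tips
    depths: Dict[int, float] = {0: 0.0}
    order = [0]
    idx = 0
    while idx < len(order):
        node = order[idx]
        idx += 1
        for c in children[node]:
            if children[c]:
                frac = float(rng.uniform(0.2, 0.8))
                depths[c] = depths[node] + frac * (spec.tmrca_years - depths[node])
            else:
                depths[c] = spec.tmrca_years
            order.append(c)
    paths: List[List[float]] = []

    def walk(node: int, acc: List[float]):
        if not children[node]:
            paths.append(acc)
            return
        for c in children[node]:
            walk(c, acc + [depths[c] - depths[node]])

    walk(0, [])
    return paths


def simulate_clade(
    spec: SimulationSpec,
    reference: Optional[ReferenceGenome] = None,
    gene_map: Optional[GeneMap] = None,
    mask: HotspotMask = DATING_MASK,
) -> SimulatedClade:
    """Simulate haplotypes of a clade with known TMRCA.

    Counted-class mutations arrive as Poisson(branch_years / clock years per
    mutation); for a synonymous clock, decoration replacement mutations are
    added at rate (1-f)/f relative to the counted class, f the synonymous
    fraction.  Infinite sites unless ``allow_recurrence``.
    """
    reference = reference or synthetic_reference()
    gene_map = gene_map or load_gene_map()
    rng = np.random.default_rng(spec.seed)
    syn_sites, rep_sites, other_sites = _SitePools.get(reference, gene_map, mask)
    ypm = spec.clock.effective_years_per_mutation
    syn_only = spec.clock.event_filter == "synonymous"

    # Infinite sites: consume a random permutation of each pool; recurrence
    # mode samples with replacement instead.
    streams = {}

    def draw_sites(pool: np.ndarray, k: int) -> List[int]:
        if spec.allow_recurrence:
            return [int(p) for p in rng.choice(pool, size=k, replace=True)]
        key = id(pool)
        if key not in streams:
            streams[key] = iter(rng.permutation(pool))
        out: List[int] = []
        try:
            for _ in range(k):
                out.append(int(next(streams[key])))
        except StopIteration:
            raise RuntimeError(
                f"mutation supply exhausted: pool of {len(pool)} sites used up"
            ) from None
        return out

    tip_paths = _branch_years(spec, rng)
    haplotypes = []
    genealogy = []
    for i, path in enumerate(tip_paths):
        sid = f"sim{i:04d}"
        total_years = sum(path)
        k_counted = int(rng.poisson(total_years / ypm))
        variants: List[Variant] = []
        if syn_only:
            variants += [Variant(p) for p in draw_sites(syn_sites, k_counted)]
            f = spec.synonymous_fraction
            k_dec = int(rng.poisson(total_years / ypm * (1 - f) / f))
            variants += [Variant(p) for p in draw_sites(rep_sites, k_dec)]
        else:
            # split counted events across classes by the synonymous fraction
            # within the coding share of eligible sites
            n_total = len(syn_sites) + len(rep_sites) + len(other_sites)
            p_coding = (len(syn_sites) + len(rep_sites)) / n_total
            for _ in range(k_counted):
                if rng.random() < p_coding:
                    pool = syn_sites if rng.random() < spec.synonymous_fraction else rep_sites
                else:
                    pool = other_sites
                variants += [Variant(p) for p in draw_sites(pool, 1)]
        haplotypes.append(Haplotype(sid, frozenset(variants), FULL_RANGE))
        genealogy.append((sid, total_years))
    root = Haplotype("clade-root", frozenset(), FULL_RANGE)
    return SimulatedClade(haplotypes, root, spec.tmrca_years, genealogy)


def recovery_experiment(
    specs: Sequence[SimulationSpec],
    replicates: int,
    seed: int = 0,
    reference: Optional[ReferenceGenome] = None,
    gene_map: Optional[GeneMap] = None,
) -> pd.DataFrame:
    """Estimator-recovery summary over a grid of simulation conditions.

    Runs the full pipeline (simulate -> parsimony genealogy -> rho/sigma ->
    clock) per replicate and reports mean TMRCA estimate, relative bias,
    RMSE and the fraction of replicates whose rho +/- 1 sigma interval
    covers the truth.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    reference = reference or synthetic_reference()
    gene_map = gene_map or load_gene_map()
    seed_rng = np.random.default_rng(seed)
    rows = []
    for cell, spec in enumerate(specs):
        est = np.empty(replicates)
        covered = 0
        for r in range(replicates):
            rep_seed = int(seed_rng.integers(0, 2 ** 31 - 1))
            sim = simulate_clade(replace(spec, seed=rep_seed), reference, gene_map)
            tree = build_parsimony_tree(sim.haplotypes, sim.root)
            kw = {}
            if spec.clock.event_filter == "synonymous":
                kw = {"gene_map": gene_map, "reference": reference}
            dists = [d for _, d in tree.root_distances(spec.clock.event_filter, **kw)]
            rho = compute_rho(dists)
            sigma = compute_sigma(tree, spec.clock.event_filter, **kw)
            t_est = rho_to_years(rho, spec.clock) * 1000.0
            lo, hi = interval_years(rho, sigma, spec.clock)
            est[r] = t_est
            if lo * 1000.0 <= spec.tmrca_years <= hi * 1000.0:
                covered += 1
        truth = spec.tmrca_years
        rows.append(
            {
                "cell": cell,
                "topology": spec.topology,
                "n": spec.n,
                "true_tmrca_years": truth,
                "clock": spec.clock.name,
                "replicates": replicates,
                "mean_tmrca_years": round(float(est.mean()), 3),
                "relative_bias": round(float((est.mean() - truth) / truth), 6)
                if truth else float("nan"),
                "rmse_years": round(float(np.sqrt(((est - truth) ** 2).mean())), 3),
                "coverage_1sigma": round(covered / replicates, 4),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Decoy databases and packaged fixture export
# ---------------------------------------------------------------------------

#: HVS-I positions commonly variable in American control-region data,
#: deliberately excluding 16124 so decoy records can never join the
#: mummy's sub-clade.
DECOY_HVS1_POOL = (
    16051, 16086, 16093, 16129, 16145, 16172, 16189, 16209, 16213, 16217,
    16234, 16249, 16256, 16261, 16270, 16274, 16278, 16290, 16291, 16293,
    16304, 16309, 16311, 16319, 16356, 16362, 16390,
)


def make_decoy_database(
    n_decoys: int,
    backbone: Sequence[Variant],
    seed: int = 0,
    mean_extra: float = 1.5,
) -> List[Haplotype]:
    """Synthetic C1b-like HVS-I records lacking 16124.

    Each decoy carries the clade backbone (restricted to its range) plus a
    Poisson number of extra variants from a 16124-free frequency pool.
    """
    rng = np.random.default_rng(seed)
    rng_range = SeqRange(16024, 16400)
    backbone_in = [v for v in backbone if rng_range.contains_variant(v)]
    out = []
    for i in range(n_decoys):
        k = min(int(rng.poisson(mean_extra)), len(DECOY_HVS1_POOL))
        extra = rng.choice(np.array(DECOY_HVS1_POOL), size=k, replace=False)
        variants = set(backbone_in) | {Variant(int(p)) for p in extra}
        out.append(
            Haplotype(f"decoy{i:04d}", frozenset(variants), rng_range,
                      population="synthetic", country="synthetic")
        )
    return out


def make_fixtures(outdir) -> Dict[str, str]:
    """Write the packaged fixtures (and the synthetic reference) to a
    directory; returns {name: path}."""
    import os

    from . import io as mio
    from .haplotree import load_toy_tree, write_tree
    from .sequences import write_fasta

    os.makedirs(outdir, exist_ok=True)
    paths = {}
    mummy, _ = mio.load_mummy_haplotype()
    p = os.path.join(outdir, "mummy_haplotype.tsv")
    mio.write_haplotype_table([mummy], p)
    paths["mummy"] = p
    related = mio.load_related_haplotypes()
    p = os.path.join(outdir, "related_hvs1.tsv")
    mio.write_haplotype_table(related, p)
    paths["related"] = p
    ops = mio.load_operator_haplotypes()
    p = os.path.join(outdir, "operators.tsv")
    mio.write_haplotype_table(ops, p)
    paths["operators"] = p
    tree = load_toy_tree()
    p = os.path.join(outdir, "toy_tree.txt")
    write_tree(tree, p)
    paths["tree"] = p
    ref = synthetic_reference()
    p = os.path.join(outdir, "synthetic_reference.fasta")
    write_fasta(ref, p, "synthetic stand-in for the rCRS (random with pinned sites)")
    paths["reference"] = p
    return paths
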