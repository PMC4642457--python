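"""rho/sigma/star-index statistics and clock conversion.

The fixed expected values are the published star-like dating rows, which
are exact rational functions of the underlying root-distance
configurations (e.g. distances {1,2} give rho=1.50, sigma=sqrt(3)/2=0.87).
"""

import math

import numpy as np
import pytest

from mtlineage import (
    CLOCKS,
    HVS1_CLOCK,
    HVS2_CLOCK,
    SYNONYMOUS_CLOCK,
    WHOLE_MOLECULE_CLOCK,
    ClockSpec,
    Haplotype,
    Variant,
    build_parsimony_tree,
    clade_report,
    compute_rho,
    compute_sigma,
    interval_years,
    load_gene_map,
    rho_to_years,
    star_index,
    synthetic_reference,
)
from mtlineage.dating import ClockError

ROOT = Haplotype("root")


def star_tree(distances, base=1000):
    """Star genealogy with the given per-tip root distances."""
    haps, pos = [], base
    for i, d in enumerate(distances):
        sites = set(range(pos, pos + d))
        pos += d
        haps.append(Haplotype(f"t{i}", {Variant(p) for p in sites}))
    return build_parsimony_tree(haps, ROOT)


class TestRho:
    @pytest.mark.parametrize(
        "distances,expected",
        [([1, 2], 1.50), ([0], 0.0), ([3, 3, 3, 2, 2], 2.60), ([2, 0, 0], 2 / 3)],
    )
    def test_mean_distance(self, distances, expected):
        assert compute_rho(distances) == pytest.approx(expected)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            compute_rho([])


class TestSigma:
    def test_two_tip_star(self):
        assert round(compute_sigma(star_tree([1, 2])), 2) == 0.87  # sqrt(3)/2

    def test_three_tip_star(self):
        assert round(compute_sigma(star_tree([6, 6, 5])), 2) == 1.37  # sqrt(17)/3

    def test_single_shared_branch(self):
        # n identical haplotypes, one branch of length l: sigma = sqrt(l)
        haps = [Haplotype(f"t{i}", {Variant(100), Variant(101)}) for i in range(5)]
        tree = build_parsimony_tree(haps, ROOT)
        assert compute_sigma(tree) == pytest.approx(math.sqrt(2))


class TestStarIndex:
    def test_three_tip_one_branch_configuration(self):
        tree = star_tree([2, 0, 0])
        rho = compute_rho([d for _, d in tree.root_distances()])
        sigma = compute_sigma(tree)
        assert round(rho, 2) == 0.67 and round(sigma, 2) == 0.47
        assert round(star_index(rho, sigma, tree.n), 1) == 1.0

    def test_published_row_value(self):
        assert round(star_index(4.29, 1.03, 7), 1) == 0.6

    def test_single_haplotype_attains_lower_bound(self):
        # all n samples one haplotype, branch length l: index = 1/n
        haps = [Haplotype(f"t{i}", {Variant(100)}) for i in range(4)]
        tree = build_parsimony_tree(haps, ROOT)
        rho = compute_rho([d for _, d in tree.root_distances()])
        sigma = compute_sigma(tree)
        assert star_index(rho, sigma, tree.n) == pytest.approx(1 / 4)

    def test_degenerate_sigma_flagged(self):
        assert math.isnan(star_index(0.0, 0.0, 3))

    @pytest.mark.parametrize("seed", range(15))
    def test_bounds_and_star_identity_on_random_trees(self, seed):
        rng = np.random.default_rng(seed)
        # random star: sigma = sqrt(rho/n) and index = 1 exactly
        distances = [int(d) for d in rng.integers(1, 6, size=rng.integers(2, 7))]
        tree = star_tree(distances)
        rho = compute_rho([d for _, d in tree.root_distances()])
        sigma = compute_sigma(tree)
        assert sigma == pytest.approx(math.sqrt(rho / tree.n))
        assert star_index(rho, sigma, tree.n) == pytest.approx(1.0)
        # random structured tree: index within [1/n, 1]
        n = int(rng.integers(2, 8))
        haps = [
            Haplotype(
                f"s{i}",
                {Variant(int(p)) for p in rng.choice(np.arange(3000, 3040),
                                                     size=rng.integers(1, 6),
                                                     replace=False)},
            )
            for i in range(n)
        ]
        t2 = build_parsimony_tree(haps, ROOT)
        r2 = compute_rho([d for _, d in t2.root_distances()])
        s2 = compute_sigma(t2)
        idx = star_index(r2, s2, t2.n)
        assert 1 / t2.n - 1e-9 <= idx <= 1 + 1e-9


class TestClocks:
    @pytest.mark.parametrize(
        "rho,clock,expected",
        [
            (0.50, SYNONYMOUS_CLOCK, 3.94),
            (2.60, SYNONYMOUS_CLOCK, 20.50),
            (0.0, SYNONYMOUS_CLOCK, 0.0),
            (1.50, WHOLE_MOLECULE_CLOCK, 5.44),
        ],
    )
    def test_rho_to_kya(self, rho, clock, expected):
        assert round(rho_to_years(rho, clock), 2) == expected

    def test_per_site_mode(self):
        # rho / (rate * sites); HVS-I partition has 350 sites
        assert rho_to_years(1.0, HVS1_CLOCK) == pytest.approx(
            1.0 / (1.64273e-7 * 350) / 1000.0
        )
        assert HVS2_CLOCK.site_count == 196

    def test_synonymous_clock_consistent_with_published_ratios(self):
        """TMRCA_syn / rho_syn = 7.884 kyr per substitution in every
        star-like published row (exact rational rho values)."""
        rows = {  # rho as exact fraction -> printed TMRCA (kya)
            (4, 3): 10.51,  # three tips {2,1,1}
            (1, 2): 3.94,   # two tips {0,1}
            (1, 4): 1.97,   # four tips {1,0,0,0}
            (1, 3): 2.63,   # three tips {1,0,0}
            (13, 5): 20.50,  # five tips {3,3,3,2,2}
        }
        for (num, den), printed in rows.items():
            assert round(rho_to_years(num / den, SYNONYMOUS_CLOCK), 2) == printed

    def test_invalid_clock_specs_rejected(self):
        with pytest.raises(ClockError):
            ClockSpec("bad", years_per_mutation=0)
        with pytest.raises(ClockError):
            ClockSpec("bad", mode="per-site-linear", rate=1e-7, site_count=0)
        with pytest.raises(ClockError):
            ClockSpec("bad", mode="quadratic", years_per_mutation=1.0)

    def test_negative_rho_rejected(self):
        with pytest.raises(ValueError):
            rho_to_years(-1.0, SYNONYMOUS_CLOCK)

    def test_registry_contains_standard_clocks(self):
        assert {"whole_molecule", "synonymous", "hvs1", "hvs2"} <= set(CLOCKS)


class TestIntervals:
    @pytest.mark.parametrize(
        "rho,sigma,expected",
        [
            (0.25, 0.25, (0.00, 3.94)),
            (0.50, 0.50, (0.00, 7.88)),
            (1.0, 0.0, (7.88, 7.88)),  # degenerate sigma
        ],
    )
    def test_one_sigma_interval(self, rho, sigma, expected):
        lo, hi = interval_years(rho, sigma, SYNONYMOUS_CLOCK)
        assert (round(lo, 2), round(hi, 2)) == expected

    def test_lower_bound_clipped_at_zero(self):
        lo, _ = interval_years(0.2, 0.9, SYNONYMOUS_CLOCK)
        assert lo == 0.0


@pytest.fixture(scope="module")
def annotation():
    return synthetic_reference(), load_gene_map()


class TestCladeReport:
    def test_two_tip_fixture_row(self, annotation):
        """Whole-variation distances {1,2}; synonymous distances {0,1}."""
        ref, gm = annotation
        syn_site, rep_site = 5135, 8584  # synonymous / replacement contexts
        haps = [
            Haplotype("a", {Variant(rep_site)}),
            Haplotype("b", {Variant(syn_site), Variant(8701)}),  # 8701: replacement
        ]
        tree = build_parsimony_tree(haps, Haplotype("root"))
        whole, syn = clade_report(
            tree, [WHOLE_MOLECULE_CLOCK, SYNONYMOUS_CLOCK], "C1b13d-like",
            gene_map=gm, reference=ref,
        )
        assert (whole.rho, whole.sigma, whole.star) == (1.50, 0.87, 1.0)
        assert (syn.rho, syn.sigma) == (0.50, 0.50)
        assert syn.tmrca_kya == 3.94
        assert syn.interval_kya == (0.00, 7.88)

    def test_single_haplotype_clade_degenerate(self, annotation):
        ref, gm = annotation
        tree = build_parsimony_tree([Haplotype("only")], Haplotype("root"))
        (row,) = clade_report(tree, [WHOLE_MOLECULE_CLOCK], gene_map=gm, reference=ref)
        assert row.rho == 0.0 and row.tmrca_kya == 0.0
        assert row.interval_kya == (0.0, 0.0)
        assert math.isnan(row.star)
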