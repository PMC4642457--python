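# Methods

## Variant model and nomenclature

Variants are single mutational events in rCRS coordinates (1-based,
circular, 16,569 bp). Transitions are written as the bare position,
transversions with a derived-base suffix (`3552A`), insertions as
`pos+bases` (second event at one site `pos.2+bases`), deletions as `posd`
or a range `290-291d`, and back mutations with an `@` prefix. Two dialects
are parsed: the compact motif style and the table style with an explicit
substitution column (`3552 T-A`). A multi-position deletion is **one**
variant and one mutational event everywhere in the package; this is the
convention under which the packaged mitogenome fixture has exactly 51
records.

Calling is alignment-based: the sample sequence is aligned to the
reference with an optimal per-base edit alignment (edlib), mismatch
regions are then re-aligned with a small gap-open dynamic program so that
substitutions are preferred over equal-cost insert+delete pairs and indel
runs form single events, and indels are left-aligned through homopolymers.
`apply_variants` is the exact inverse on left-aligned haplotypes; the
round-trip identity is property-tested.

### Hotspot mask

The default mask removes 16519, the transversions 16182C and 16183C, all
variation in 303–315 (the poly-C tract around 310) and in 523–524. The
dating mask additionally removes all indels. Masking is idempotent and
applied before classification, tree building, dating and database
matching.

## Haplogroup trees and classification

Trees are plain text, one node per line, hierarchy by indentation, each
node carrying its edge motif in compact notation. A node's cumulative
motif is the root-to-node concatenation with back mutations cancelling.
Classification scores every node as
(#matched defining variants) − (#missing defining variants within the
sample's sequenced range); motif variants outside the sequenced range are
ignored rather than penalised, which makes control-region-only records
classifiable. Ties break toward greater depth, then lexicographic name —
deterministic, but it means a sub-clade whose whole motif lies outside the
sequenced range wins over its parent; the score itself is identical, so
this is a reporting convention, not an evidence claim.

The scoring rule is the minimal one consistent with motif-based
haplogrouping; no likelihood model is attempted. Private mutations are the
masked sample variants absent from the best node's cumulative motif.

The packaged toy tree chains the rCRS (an H2a2a lineage) through
HV/R0/R/N/L3/M/M8/CZ/C/C1 to C1b using the lineage assignments of the
fixture's non-private variants; the H1 branch and the sub-clades below C1b
carry illustrative placeholder motifs so that sister-clade and
contamination behaviour can be exercised. Full-scale trees load through
the same format.

### Phylogeny-aware nomenclature

Where an indel region admits several alignment-equivalent variant
representations, `resolve_nomenclature` reconstructs the local sample
sequence, enumerates every representation within roughly one extra event's
alignment cost of the optimum, and picks the one maximising the number of
variants present anywhere in the tree's motif vocabulary; ties break
toward fewer events, then leftmost placement. This reproduces the standard
practice of preferring, e.g., `56T 57 60+T` over the more parsimonious
`56T 56+C` when 57 and 60+T are established motifs.

### Subclade discovery and contamination checks

Proposed sub-clades are the closed sets of private variants shared by at
least two haplotypes under a node (exact closed-itemset enumeration, so
the output provably equals brute-force enumeration of shared subsets;
nested sharing yields nested proposals). The contamination cross-check
places sample and operator haplotypes on the tree, extends each placement
by a virtual private branch when private mutations exist, and calls the
pair incompatible whenever neither effective root path is a prefix of the
other — i.e. the lineages demonstrably diverge below their deepest common
ancestor.

## Parsimony genealogies

Within-clade genealogies are built by greedy agglomeration of shared
derived variants (most widely shared first, ties by position): derived
states are computed against the masked clade root, haplotypes identical
after masking merge into one tip with multiplicity, and variants shared by
every member of a group move onto the group's stem branch. On
pairwise-compatible (perfect-phylogeny) data — the regime mtDNA clades
approximate and the synthetic generator produces under infinite sites —
the greedy tree attains the exact minimum length; the test suite checks
this against an independent exhaustive Fitch search over all rooted
topologies for ≤6 haplotypes and ≤10 segregating sites, and conflicting
characters are handled by recurrence labelling. Root distances can be
filtered to synonymous events (requires the gene map and reference for
codon translation). Both tree-based and direct haplotype-vs-root distances
are exposed; they coincide on star-like data.

## Dating

ρ is the multiplicity-weighted mean root distance; σ = (1/n)√(Σ l_b·n_b²);
the star index is ρ/(n·σ²) (NaN when σ = 0, e.g. a single-haplotype
clade). Clock constants:

| clock | mode | constant | counted events |
|---|---|---|---|
| whole_molecule | per molecule | 3624 yr/mutation | all |
| synonymous | per molecule | 7884 yr/substitution | synonymous only |
| hvs1 | per site | 1.64273×10⁻⁷ /site/yr × 350 sites (16051–16400) | all |
| hvs2 | per site | 2.2964×10⁻⁷ /site/yr × 196 sites (68–263) | all |

Two published whole-molecule figures are mutually inconsistent: a
per-site rate of 1.16649×10⁻⁸ /site/yr implies ~5173 yr/mutation over
16,569 sites, not the equally published "one mutation every 3624 years".
The package pins the per-molecule equivalence (3624) for the linear clock;
the per-site mode accepts any user-supplied rate. The synonymous constant
7884 yr/substitution reproduces every star-like synonymous table row
exactly (TMRCA/ρ = 7.884 kyr in each), which is asserted in a test. A
purifying-selection-corrected whole-molecule conversion (used by the
published whole-variation ages) is *not* bundled; whole-molecule linear
ages therefore differ from corrected published values and are not treated
as reproduction targets.

Intervals are ρ±1σ through the clock, clipped at zero. They match the
published synonymous-column "95% CI" bounds exactly, which empirically
equal TMRCA ± σ·clock — a ±1σ (~68%) interval despite the column label;
the label is reproduced as a label only. Report rounding follows table
precision: ρ, σ, ages 2 dp; star index 1 dp.

## Database search and kriging

Motif search requires every backbone and required variant to be present
within each record's sequenced range; variants outside a record's range
neither match nor exclude it, and masked variants are ignored on both
sides (so a 16183C carrier matches a motif that omits it). An inverted
position index accelerates candidate lookup; correctness against a naive
scan is tested.

Frequency surfaces use ordinary kriging on great-circle (haversine)
distances: weights solve the standard constrained system (Σw = 1, enforced
to machine precision), an exponential variogram is the default with
range/sill fitted by method-of-moments on the empirical semivariogram when
not supplied, nugget 0 gives exact interpolation at data points, and
output is clipped to [0,1]. Coincident input points are reported as a
singular-system error naming the pair.

## Synthetic data

The generator emulates the mutation-accumulation model ρ dating assumes:
counted-class mutations arrive along each branch as Poisson(branch years /
clock years-per-mutation), positions drawn without replacement (infinite
sites; a recurrence flag relaxes this), on a star or Yule-like ultrametric
topology. For synonymous clocks, counted events land on sites where a
transition is synonymous (computed from the gene map and reference under
the vertebrate mitochondrial code) and replacement-site decoration is
added at rate (1−f)/f so the synonymous fraction of coding mutations
matches the spec (default 0.55, a realistic within-clade value for this
locus). Positions are uniform within each functional class rather than
across the whole molecule — the class fractions, which is what dating is
sensitive to, are thereby exact in expectation. All randomness flows from
a single seed; equal seeds give identical output.

The packaged reference is a deterministic **synthetic** 16,569-base
stand-in for the rCRS: random bases with ~80 pinned positions so the
fixtures' ancestral alleles, codon effects (e.g. 8584 Ala→Thr, 14318
Asn→Ser on the light strand, 7028 synonymous) and indel contexts reproduce
exactly. Analyses of real data should load the true rCRS. Because the
filler is random, genome-wide codon statistics (e.g. the true synonymous
site density) are not those of the real molecule — passing tests validate
the machinery and the estimator's statistical behaviour, not organism-level
site counts. Protein features in the gene map are trimmed to whole codons
(incomplete stop codons excluded).

Decoy database records for search experiments carry the clade backbone
plus extra HVS-I variants drawn from a frequency pool that deliberately
excludes 16124, so the planted-membership search has an unambiguous truth.

## Validation experiments and problem sizes

`recovery_experiment` runs the full pipeline per replicate. The packaged
validation uses star clades with n = 20 tips, true TMRCA 10 kya,
synonymous clock, 1000 replicates: relative bias is within ±3% (the ρ
estimator is unbiased for Poisson counts; the Monte-Carlo standard error
of the mean at this size is ~0.6%) and the ±1σ interval covers the truth
in 62–74% of replicates (normal-approximation 68% coverage). The
parsimony-optimality check uses 1000 simulated instances with ≤6
haplotypes and ≤10 segregating sites, the exhaustive-search oracle being
exact at that size. These sizes were chosen so each check is statistically
decisive while the whole suite runs in well under a minute.

## Known limitations

- Classification is motif-counting, not likelihood placement; deeply
  ambiguous placements rely on the deterministic tie-break.
- The greedy parsimony builder is exact only for compatible characters;
  heavily recurrent data can exceed the optimum (recurrences are labelled,
  not re-searched).
- Heteroplasmy, mixtures and read-level data are out of scope; inputs are
  consensus haplotypes.
- The nomenclature resolver explores a bounded window (±8 bp around each
  indel) and one extra event of slack; pathological tandem-repeat regions
  beyond that are left as called.
- Kriging treats frequencies as Gaussian-ish observations without
  sample-size weighting; the `sample_size` field is carried but not yet
  used for error variances.
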