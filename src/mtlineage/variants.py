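"""Variant and haplotype data model for human mitochondrial DNA.

Variants are named against the revised Cambridge Reference Sequence (rCRS)
in forensic convention: 1-based positions on a circular 16,569-base
molecule, transitions written as the bare position (``16223``), transversions
with the derived base as a suffix (``3552A``), insertions with ``+`` and the
inserted bases (``309+C``, second event at a site ``309.2+C``), deletions
with ``d`` (``249d``) or a range (``290-291d``, one mutational event), and a
``@`` prefix for back mutations.

Hotspot masking follows the usual dating convention for this locus:
16182C, 16183C, 16519, length variation in the 303-315 poly-C tract and the
523-524 AC deletion are excluded, and indels are additionally dropped when a
mask with ``mask_indels`` is applied.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from typing import Iterable, Optional

RCRS_LENGTH = 16569

TRANSITION = "transition"
TRANSVERSION = "transversion"
INSERTION = "insertion"
DELETION = "deletion"
KINDS = (TRANSITION, TRANSVERSION, INSERTION, DELETION)

_PURINE_FLIP = {"A": "G", "G": "A", "C": "T", "T": "C"}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}
_BASES = frozenset("ACGT")


class NotationError(ValueError):
    """Raised for malformed variant tokens; the message names the token."""


def transition_of(base: str) -> str:
    """Return the transition partner of a base (A<->G, C<->T)."""
    return _PURINE_FLIP[base.upper()]


def complement(base: str) -> str:
    return _COMPLEMENT[base.upper()]


@dataclass(frozen=True, order=True)
class Variant:
    """One mutational event in rCRS coordinates.

    ``derived_allele`` carries the derived base for transversions and the
    inserted bases for insertions; transitions flip the reference base and
    store nothing, deletions store nothing.  ``end_position`` exceeds
    ``position`` only for multi-base deletions, which count as a single
    event throughout.
    """

    position: int
    kind: str = TRANSITION
    end_position: int = 0
    derived_allele: str = ""
    back_mutation: bool = False
    inserted_index: int = 1

    def __post_init__(self):
        if self.end_position == 0:
            object.__setattr__(self, "end_position", self.position)
        if not 1 <= self.position:
            raise NotationError(f"position {self.position} is not a valid 1-based coordinate")
        if self.kind not in KINDS:
            raise NotationError(f"unknown variant kind {self.kind!r}")
        if self.end_position < self.position:
            raise NotationError(
                f"deletion range reversed: {self.position}-{self.end_position}"
            )
        if self.end_position > self.position and self.kind != DELETION:
            raise NotationError("end_position > position is only valid for deletions")
        if self.kind in (TRANSVERSION, INSERTION):
            if not self.derived_allele or not set(self.derived_allele) <= _BASES:
                raise NotationError(
                    f"{self.kind} at {self.position} needs a derived allele in ACGT, "
                    f"got {self.derived_allele!r}"
                )
            if self.kind == TRANSVERSION and len(self.derived_allele) != 1:
                raise NotationError(
                    f"transversion at {self.position} must carry a single base"
                )
        elif self.derived_allele:
            raise NotationError(f"{self.kind} at {self.position} must not carry an allele")

    @property
    def is_indel(self) -> bool:
        return self.kind in (INSERTION, DELETION)

    @property
    def key(self):
        """Identity used for set membership inside a haplotype."""
        return (self.position, self.kind, self.inserted_index)

    def spans(self, pos: int) -> bool:
        return self.position <= pos <= self.end_position

    def __str__(self) -> str:
        return format_variant(self)


def format_variant(v: Variant, dialect: str = "compact") -> str:
    """Render a variant token; inverse of :func:`parse_variant`."""
    prefix = "@" if v.back_mutation else ""
    if dialect == "table":
        core = format_variant(replace(v, back_mutation=False), "compact")
        return prefix + core
    if v.kind == DELETION:
        if v.end_position > v.position:
            return f"{prefix}{v.position}-{v.end_position}d"
        return f"{prefix}{v.position}d"
    if v.kind == INSERTION:
        idx = f".{v.inserted_index}" if v.inserted_index != 1 else ""
        return f"{prefix}{v.position}{idx}+{v.derived_allele}"
    if v.kind == TRANSVERSION:
        return f"{prefix}{v.position}{v.derived_allele}"
    return f"{prefix}{v.position}"


_COMPACT_RE = re.compile(
    r"""^(?P<back>@?)
         (?P<pos>\d+)
         (?:
            [-–](?P<end>\d+)d            # range deletion, hyphen or en-dash
          | (?P<del>d)
          | (?:\.(?P<idx>\d+))?\+(?P<ins>[ACGTacgt]+)
          | (?P<tv>[ACGTacgt])
         )?$""",
    re.VERBOSE,
)


def parse_variant(token: str, dialect: str = "compact") -> Variant:
    """Parse a variant token in either notation dialect.

    ``compact`` is the motif style (``3552A``, ``290-291d``, ``@16223``);
    ``table`` is the two-column style with an explicit substitution, e.g.
    ``"3552 T-A"`` or ``"309 + C"``.
    """
    token = token.strip()
    if not token:
        raise NotationError("empty variant token")
    if dialect == "table":
        return _parse_table(token)
    if dialect != "compact":
        raise NotationError(f"unknown dialect {dialect!r}")
    m = _COMPACT_RE.match(token)
    if not m:
        raise NotationError(f"unparseable variant token {token!r}")
    pos = int(m.group("pos"))
    back = bool(m.group("back"))
    if m.group("end"):
        return Variant(pos, DELETION, end_position=int(m.group("end")), back_mutation=back)
    if m.group("del"):
        return Variant(pos, DELETION, back_mutation=back)
    if m.group("ins"):
        idx = int(m.group("idx")) if m.group("idx") else 1
        return Variant(pos, INSERTION, derived_allele=m.group("ins").upper(),
                       back_mutation=back, inserted_index=idx)
    if m.group("tv"):
        return Variant(pos, TRANSVERSION, derived_allele=m.group("tv").upper(),
                       back_mutation=back)
    return Variant(pos, TRANSITION, back_mutation=back)


def _parse_table(token: str) -> Variant:
    # Normalise "309 + C" -> "309+C"; split off a trailing substitution column.
    text = re.sub(r"\s*\+\s*", "+", token.replace("–", "-"))
    parts = text.split()
    core = parts[0]
    if len(parts) > 2:
        raise NotationError(f"unparseable table token {token!r}")
    sub = parts[1] if len(parts) == 2 else ""
    if sub in ("-", "−", ""):
        sub = ""
    back = core.startswith("@")
    if back:
        core = core[1:]
    if core.endswith("d") or "+" in core:
        v = parse_variant(("@" if back else "") + core)
        if sub:
            raise NotationError(f"indel token {token!r} must not carry a substitution")
        return v
    if not core.isdigit():
        raise NotationError(f"malformed position in {token!r}")
    pos = int(core)
    if not sub:
        return Variant(pos, TRANSITION, back_mutation=back)
    msub = re.match(r"^([ACGTacgt])-([ACGTacgt])$", sub)
    if not msub:
        raise NotationError(f"malformed substitution {sub!r} in {token!r}")
    ref, alt = msub.group(1).upper(), msub.group(2).upper()
    if transition_of(ref) == alt:
        return Variant(pos, TRANSITION, back_mutation=back)
    return Variant(pos, TRANSVERSION, derived_allele=alt, back_mutation=back)


@dataclass(frozen=True)
class SeqRange:
    """1-based inclusive rCRS coordinate range; start > end wraps the origin."""

    start: int
    end: int

    def __post_init__(self):
        if not (1 <= self.start <= RCRS_LENGTH and 1 <= self.end <= RCRS_LENGTH):
            raise ValueError(f"range {self.start}-{self.end} outside 1..{RCRS_LENGTH}")

    @property
    def wraps(self) -> bool:
        return self.start > self.end

    def contains(self, pos: int) -> bool:
        if self.wraps:
            return pos >= self.start or pos <= self.end
        return self.start <= pos <= self.end

    def contains_variant(self, v: Variant) -> bool:
        return self.contains(v.position) and self.contains(v.end_position)

    def intervals(self, length: int = RCRS_LENGTH):
        """Linear (start, end) pieces covered by the range."""
        if self.wraps:
            return [(self.start, length), (1, self.end)]
        return [(self.start, self.end)]

    def size(self, length: int = RCRS_LENGTH) -> int:
        return sum(e - s + 1 for s, e in self.intervals(length))

    def overlaps(self, other: "SeqRange", length: int = RCRS_LENGTH) -> bool:
        for s1, e1 in self.intervals(length):
            for s2, e2 in other.intervals(length):
                if s1 <= e2 and s2 <= e1:
                    return True
        return False

    def __str__(self) -> str:
        return f"{self.start}-{self.end}"

    @classmethod
    def parse(cls, text: str) -> "SeqRange":
        m = re.match(r"^\s*(\d+)\s*[-–]\s*(\d+)\s*$", text)
        if not m:
            raise ValueError(f"unparseable sequence range {text!r}")
        return cls(int(m.group(1)), int(m.group(2)))


FULL_RANGE = SeqRange(1, RCRS_LENGTH)


@dataclass(frozen=True)
class Haplotype:
    """A sample's variant set over a sequenced range, with metadata."""

    sample_id: str
    variants: frozenset = frozenset()
    range: SeqRange = FULL_RANGE
    population: Optional[str] = None
    country: Optional[str] = None
    period: Optional[str] = None

    def __post_init__(self):
        object.__setattr__(self, "variants", frozenset(self.variants))
        keys = [v.key for v in self.variants]
        if len(keys) != len(set(keys)):
            raise ValueError(f"{self.sample_id}: duplicate variant at one (position, kind)")
        for v in self.variants:
            if not self.range.contains_variant(v):
                raise ValueError(
                    f"{self.sample_id}: variant {v} outside sequenced range {self.range}"
                )

    def __len__(self) -> int:
        return len(self.variants)

    def with_variants(self, variants: Iterable[Variant]) -> "Haplotype":
        return replace(self, variants=frozenset(variants))

    def sorted_variants(self):
        return sorted(self.variants)

    def tokens(self) -> str:
        return " ".join(str(v) for v in self.sorted_variants())


@dataclass(frozen=True)
class HotspotMask:
    """Positions, position/allele pairs and regions excluded from analysis.

    A variant is masked when it hits any entry, or when it is an indel and
    ``mask_indels`` is set (the dating convention).
    """

    positions: frozenset = frozenset()
    alleles: frozenset = frozenset()  # (position, derived base) pairs
    regions: tuple = ()
    mask_indels: bool = False

    def matches(self, v: Variant) -> bool:
        if self.mask_indels and v.is_indel:
            return True
        for p in range(v.position, v.end_position + 1):
            if p in self.positions:
                return True
            if any(r.contains(p) for r in self.regions):
                return True
        if v.kind == TRANSVERSION and (v.position, v.derived_allele) in self.alleles:
            return True
        return False

    def with_indels(self, mask_indels: bool = True) -> "HotspotMask":
        return replace(self, mask_indels=mask_indels)


#: The default exclusion list: 16182C, 16183C, 16519, variation around the
#: 303-315 poly-C tract, and the 523-524 AC deletion.
DEFAULT_MASK = HotspotMask(
    positions=frozenset({16519}),
    alleles=frozenset({(16182, "C"), (16183, "C")}),
    regions=(SeqRange(303, 315), SeqRange(523, 524)),
)

#: Mask used for tree building and dating: the default list plus all indels.
DATING_MASK = DEFAULT_MASK.with_indels(True)

EMPTY_MASK = HotspotMask()


def mask_hotspots(haplotype: Haplotype, mask: HotspotMask = DEFAULT_MASK) -> Haplotype:
    """Return a copy of the haplotype with masked variants removed."""
    return haplotype.with_variants(v for v in haplotype.variants if not mask.matches(v))


def mutational_distance(
    a: Haplotype,
    b: Haplotype,
    count_indels: bool = True,
    mask: HotspotMask = EMPTY_MASK,
) -> int:
    """Number of mutational events separating two haplotypes.

    The comparison is restricted to the intersection of the two sequenced
    ranges; each deletion range counts as one event; indels can be excluded
    wholesale (the common dating practice).
    """
    if not a.range.overlaps(b.range):
        raise ValueError(f"ranges {a.range} and {b.range} are disjoint")

    def usable(v: Variant) -> bool:
        if mask.matches(v):
            return False
        if not count_indels and v.is_indel:
            return False
        return a.range.contains_variant(v) and b.range.contains_variant(v)

    return len({v for v in (a.variants ^ b.variants) if usable(v)})
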