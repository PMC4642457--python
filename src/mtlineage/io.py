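"""Tab-delimited haplotype tables (EMPOP-style) and packaged fixture loaders.

A haplotype table is UTF-8, '#'-commented, tab-delimited with a header row:
``sample_id  population  country  [period]  range  variants  [private]`` —
``range`` like ``16024-16569`` (hyphen or en-dash) and ``variants`` a
space-separated list of compact tokens.
"""

from __future__ import annotations

from importlib import resources
from typing import List, Optional, Tuple

import pandas as pd

from .variants import Haplotype, SeqRange, parse_variant


def _parse_tokens(text: str) -> frozenset:
    text = (text or "").strip()
    if not text:
        return frozenset()
    return frozenset(parse_variant(tok) for tok in text.split())


def read_haplotype_table(path_or_buf) -> List[Haplotype]:
    """Read a haplotype table into :class:`Haplotype` records."""
    df = read_haplotype_frame(path_or_buf)
    out = []
    for r in df.itertuples():
        out.append(
            Haplotype(
                sample_id=str(r.sample_id),
                variants=_parse_tokens(r.variants),
                range=SeqRange.parse(str(r.range)),
                population=_opt(getattr(r, "population", None)),
                country=_opt(getattr(r, "country", None)),
                period=_opt(getattr(r, "period", None)),
            )
        )
    return out


def read_haplotype_frame(path_or_buf) -> pd.DataFrame:
    """Raw table as a DataFrame (keeps extra columns such as ``private``)."""
    df = pd.read_csv(path_or_buf, sep="\t", comment="#", dtype=str)
    required = {"sample_id", "range", "variants"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"haplotype table missing columns: {sorted(missing)}")
    return df.fillna("")


def write_haplotype_table(haplotypes, path) -> None:
    rows = []
    for h in haplotypes:
        rows.append(
            {
                "sample_id": h.sample_id,
                "population": h.population or "",
                "country": h.country or "",
                "period": h.period or "",
                "range": str(h.range),
                "variants": h.tokens(),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _opt(value) -> Optional[str]:
    value = (value or "").strip()
    return value or None


def _packaged(name: str):
    return resources.files("mtlineage.data").joinpath(name)


def load_mummy_haplotype() -> Tuple[Haplotype, frozenset]:
    """The packaged complete-mitogenome mummy haplotype.

    Returns the haplotype (51 variants) and the set of variants flagged
    private within C1b in the source table (10 variants).
    """
    with _packaged("mummy_table1.tsv").open() as fh:
        df = read_haplotype_frame(fh)
    with _packaged("mummy_table1.tsv").open() as fh:
        h = read_haplotype_table(fh)[0]
    private = _parse_tokens(df.iloc[0]["private"])
    return h, private


def load_related_haplotypes() -> List[Haplotype]:
    """The packaged HVS-I table of haplotypes related to the mummy's clade.

    Variant sets are relative to the C1b root haplotype, as printed; compose
    with the C1b cumulative motif (``phylogeo.expand_from_root``) for
    rCRS-relative records.
    """
    with _packaged("related_hvs1_table3.tsv").open() as fh:
        return read_haplotype_table(fh)


def load_operator_haplotypes() -> List[Haplotype]:
    """Synthetic lab-operator haplotypes for contamination cross-checks."""
    with _packaged("operator_haplotypes.tsv").open() as fh:
        return read_haplotype_table(fh)


def packaged_tree_text() -> str:
    return _packaged("toy_haplogroup_tree.txt").read_text()
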