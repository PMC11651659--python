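"""Suppressor-screen variant filtering.

Whole-genome sequencing of independently isolated suppressor colonies
against a non-isogenic reference yields thousands of shared background
SNPs.  The screen subtracts a background set — the union of the variant
calls of two colonies isolated on different plates, so a true suppressor
mutation is unlikely to be present in both — leaving a small per-colony
unique set, which is then annotated for overlap with genes of interest
(splicing factors first).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .errors import ConfigurationError, ParseError

log = logging.getLogger(__name__)

#: variant identity key
VariantKey = tuple[str, int, str, str]


@dataclass(frozen=True)
class VariantRecord:
    colony_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    effect_note: str = ""

    def __post_init__(self):
        if self.pos < 1:
            raise ParseError(f"position {self.pos} < 1")
        if self.ref == self.alt:
            raise ParseError(f"ref equals alt at {self.chrom}:{self.pos}")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class GeneInterval:
    gene_id: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    category: str = ""

    def __post_init__(self):
        if self.start > self.end:
            raise ParseError(f"{self.gene_id}: start > end")


def read_variants(path, colony_id: str | None = None) -> list[VariantRecord]:
    """Read a variant TSV (header: colony_id, chrom, pos, ref, alt[, effect_note])
    or a minimal VCF fragment (CHROM, POS, REF, ALT used; other columns and
    header lines ignored; ``colony_id`` required).  Duplicate keys within a
    colony are dropped with a warning."""
    path = Path(path)
    first = ""
    with open(path) as fh:
        for line in fh:
            if line.strip():
                first = line
                break
    records: list[VariantRecord] = []
    if first.startswith("#") or first.startswith("##"):
        if colony_id is None:
            raise ConfigurationError("VCF input requires an explicit colony_id")
        with open(path) as fh:
            for line_no, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 5:
                    raise ParseError("VCF line with <5 columns", path=path, line_no=line_no)
                try:
                    pos = int(fields[1])
                except ValueError:
                    raise ParseError(f"malformed position {fields[1]!r}", path=path, line_no=line_no)
                records.append(
                    VariantRecord(colony_id=colony_id, chrom=fields[0], pos=pos,
                                  ref=fields[3], alt=fields[4])
                )
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = ["colony_id", "chrom", "pos", "ref", "alt"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ParseError(f"variant table missing columns {missing}", path=path)
        for i, row in enumerate(df.itertuples(index=False), start=2):
            try:
                pos = int(row.pos)
            except ValueError:
                raise ParseError(f"malformed position {row.pos!r}", path=path, line_no=i)
            records.append(
                VariantRecord(
                    colony_id=row.colony_id, chrom=row.chrom, pos=pos,
                    ref=row.ref, alt=row.alt,
                    effect_note=getattr(row, "effect_note", "") or "",
                )
            )
    # per-colony dedup with warning
    seen: set[tuple[str, VariantKey]] = set()
    out = []
    for rec in records:
        ident = (rec.colony_id, rec.key)
        if ident in seen:
            log.warning("duplicate variant %s in colony %s dropped", rec.key, rec.colony_id)
            continue
        seen.add(ident)
        out.append(rec)
    return out


def group_by_colony(records: Iterable[VariantRecord]) -> dict[str, set[VariantKey]]:
    sets: dict[str, set[VariantKey]] = {}
    for rec in records:
        sets.setdefault(rec.colony_id, set()).add(rec.key)
    return sets


def subtract_recurrent(
    colony_sets: Mapping[str, set[VariantKey]],
    background_colonies: Sequence[str],
    plates: Mapping[str, str] | None = None,
) -> dict[str, set[VariantKey]]:
    """Subtract the recurrent-SNP background from every colony's variant set.

    The background is the union of the variant keys of
    ``background_colonies`` (default reading: two colonies from different
    plates; any number is accepted).  For a colony that is itself part of
    the background, its unique set is its keys minus the union of the
    *other* background colonies, so its own suppressor candidates are not
    self-subtracted.  If ``plates`` is given and all background colonies
    share one plate, that defeats the purpose of the pairing and is a
    configuration error.
    """
    for cid in background_colonies:
        if cid not in colony_sets:
            raise ConfigurationError(f"background colony {cid!r} not among colonies")
    if plates is not None and len(background_colonies) > 1:
        bg_plates = {plates[c] for c in background_colonies}
        if len(bg_plates) == 1:
            raise ConfigurationError(
                "background colonies must come from different plates"
            )
    unique: dict[str, set[VariantKey]] = {}
    for cid, keys in colony_sets.items():
        others = [b for b in background_colonies if b != cid]
        background: set[VariantKey] = set()
        for b in others:
            background |= colony_sets[b]
        unique[cid] = set(keys) - background
    return unique


def annotate_gene_overlap(
    unique_sets: Mapping[str, set[VariantKey]],
    intervals: Sequence[GeneInterval],
    priority_category: str = "splicing factor",
) -> pd.DataFrame:
    """Label each unique variant with overlapping genes (inclusive bounds).

    Variants in no interval are labeled ``intergenic``.  Within each
    colony, variants hitting the priority category are listed first.
    """
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end + 1, iv)
    rows = []
    for cid in sorted(unique_sets):
        for key in sorted(unique_sets[cid]):
            chrom, pos, ref, alt = key
            hits = sorted(
                (h.data for h in trees.get(chrom, IntervalTree()).at(pos)),
                key=lambda iv: iv.gene_id,
            )
            genes = ";".join(iv.gene_id for iv in hits) or "intergenic"
            categories = ";".join(iv.category for iv in hits if iv.category)
            rows.append(
                {
                    "colony_id": cid, "chrom": chrom, "pos": pos, "ref": ref,
                    "alt": alt, "genes": genes, "category": categories,
                    "priority": int(priority_category in [iv.category for iv in hits]),
                }
            )
    df = pd.DataFrame(
        rows, columns=["colony_id", "chrom", "pos", "ref", "alt", "genes", "category", "priority"]
    )
    if len(df):
        df = df.sort_values(
            ["colony_id", "priority", "chrom", "pos"], ascending=[True, False, True, True]
        ).reset_index(drop=True)
    return df
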