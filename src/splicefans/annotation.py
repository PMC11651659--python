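"""Intron annotation, junction-to-gene assignment and canonical-site calling.

The annotation table follows a minimal TSV schema modeled on curated
yeast intron catalogs: one row per intron with gene, gene class
(``RPG``/``non-RPG``/``other``), strand, 1-based inclusive intron bounds
and the annotated branch-point adenosine position.

Assignment places each stranded junction with the annotated intron whose
extended window contains both junction ends; the canonical junction per
intron is then called as the one with the highest pooled unique-read
count across genotypes, so a single canonical site anchors the
between-genotype comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .errors import ParseError
from .junctions import JunctionKey, JunctionRecord, JunctionTable

log = logging.getLogger(__name__)

_GENE_CLASSES = {"RPG", "non-RPG", "other"}

ANNOTATION_COLUMNS = [
    "gene_id", "gene_class", "chrom", "strand",
    "intron_index", "intron_start", "intron_end", "bp_pos",
]


@dataclass(frozen=True)
class IntronAnnotation:
    """One annotated intron with its canonical splice sites and branch point."""

    gene_id: str
    gene_class: str
    chrom: str
    strand: str
    intron_index: int
    intron_start: int
    intron_end: int
    bp_pos: int

    def __post_init__(self):
        if self.strand not in {"+", "-"}:
            raise ParseError(f"{self.gene_id}: unknown strand {self.strand!r}")
        if not self.intron_start <= self.bp_pos <= self.intron_end:
            raise ParseError(
                f"{self.gene_id}: bp_pos {self.bp_pos} outside intron "
                f"[{self.intron_start},{self.intron_end}]"
            )
        if self.gene_class not in _GENE_CLASSES:
            raise ParseError(f"{self.gene_id}: unknown gene_class {self.gene_class!r}")

    @property
    def donor_pos(self) -> int:
        return self.intron_start if self.strand == "+" else self.intron_end

    @property
    def acceptor_pos(self) -> int:
        """Canonical 3'SS: last intron base in transcript direction."""
        return self.intron_end if self.strand == "+" else self.intron_start


def read_intron_table(path) -> list[IntronAnnotation]:
    """Load the intron annotation TSV, validating each row's invariants."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene_id": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"annotation table missing columns {missing}", path=path)
    out: list[IntronAnnotation] = []
    seen: set[tuple[str, int]] = set()
    for row in df.itertuples(index=False):
        ann = IntronAnnotation(
            gene_id=row.gene_id, gene_class=row.gene_class, chrom=row.chrom,
            strand=row.strand, intron_index=int(row.intron_index),
            intron_start=int(row.intron_start), intron_end=int(row.intron_end),
            bp_pos=int(row.bp_pos),
        )
        ident = (ann.gene_id, ann.intron_index)
        if ident in seen:
            raise ParseError(f"duplicate intron {ident}", path=path)
        seen.add(ident)
        out.append(ann)
    return out


def write_intron_table(annotations: Sequence[IntronAnnotation], path) -> None:
    pd.DataFrame([vars(a) for a in annotations])[ANNOTATION_COLUMNS].to_csv(
        path, sep="\t", index=False
    )


@dataclass
class GeneJunctionSet:
    """Junctions assigned to one annotated intron in one genotype.

    After canonical calling, ``alt3`` holds junctions sharing the
    canonical 5'SS with an alternative 3'SS, ``alt5`` the converse, and
    ``neither`` junctions matching neither canonical end.
    """

    annotation: IntronAnnotation
    records: dict[JunctionKey, JunctionRecord] = field(default_factory=dict)
    canonical: JunctionKey | None = None
    alt3: list[JunctionKey] = field(default_factory=list)
    alt5: list[JunctionKey] = field(default_factory=list)
    neither: list[JunctionKey] = field(default_factory=list)

    def count(self, key: JunctionKey) -> int:
        rec = self.records.get(key)
        return 0 if rec is None else rec.unique_reads


def _junction_ends(key: JunctionKey) -> tuple[int, int]:
    return key[1], key[2]


def _donor_acceptor(key: JunctionKey) -> tuple[int, int]:
    chrom, start, end, strand = key
    return (start, end) if strand == "+" else (end, start)


def assign_junctions_to_genes(
    merged_tables: Mapping[str, JunctionTable],
    annotations: Sequence[IntronAnnotation],
    *,
    window: int = 500,
) -> tuple[dict[str, dict[tuple[str, int], GeneJunctionSet]], dict[str, int]]:
    """Assign merged junctions to annotated introns, per genotype.

    A junction is assigned when it lies on the intron's chromosome and
    strand and both its ends fall within the intron extended by
    ``window`` nt on each side.  Among multiple matching introns of the
    same gene the one with the nearest donor wins; junctions matching
    introns of different genes are ambiguous and dropped.  Strand-unknown
    junctions are dropped.  Returns (assignments, drop counters).
    """
    by_loc: dict[tuple[str, str], list[IntronAnnotation]] = {}
    for ann in annotations:
        by_loc.setdefault((ann.chrom, ann.strand), []).append(ann)

    counters = {"strand_unknown": 0, "unassigned": 0, "ambiguous": 0, "assigned": 0}
    assignments: dict[str, dict[tuple[str, int], GeneJunctionSet]] = {}
    for genotype, table in merged_tables.items():
        gsets: dict[tuple[str, int], GeneJunctionSet] = {}
        for rec in table:
            if rec.strand == ".":
                counters["strand_unknown"] += 1
                continue
            candidates = [
                ann
                for ann in by_loc.get((rec.chrom, rec.strand), [])
                if ann.intron_start - window <= rec.intron_start
                and rec.intron_end <= ann.intron_end + window
            ]
            if not candidates:
                counters["unassigned"] += 1
                continue
            genes = {a.gene_id for a in candidates}
            if len(genes) > 1:
                counters["ambiguous"] += 1
                continue
            # nearest intron of the gene by donor distance (multi-intron genes)
            ann = min(candidates, key=lambda a: abs(a.donor_pos - rec.donor_pos))
            ident = (ann.gene_id, ann.intron_index)
            gsets.setdefault(ident, GeneJunctionSet(annotation=ann)).records[rec.key] = rec
            counters["assigned"] += 1
        assignments[genotype] = gsets
    if counters["strand_unknown"] or counters["unassigned"] or counters["ambiguous"]:
        log.info(
            "junction assignment dropped %d strand-unknown, %d unassigned, %d ambiguous",
            counters["strand_unknown"], counters["unassigned"], counters["ambiguous"],
        )
    return assignments, counters


def call_canonical_sites(
    assignments: Mapping[str, dict[tuple[str, int], GeneJunctionSet]],
    *,
    pool_genotypes: bool = True,
) -> None:
    """Fix the canonical junction per intron and partition the others, in place.

    The canonical junction is the assigned junction with the maximal
    unique-read count, pooled across genotypes by default so the same
    canonical site anchors both strains.  Ties break toward the junction
    matching the annotated intron bounds, then toward the smallest
    genomic coordinates; the tie-break is total, so input order never
    matters.
    """
    idents: list[tuple[str, int]] = []
    for gsets in assignments.values():
        for ident in gsets:
            if ident not in idents:
                idents.append(ident)

    for ident in idents:
        holders = [g[ident] for g in assignments.values() if ident in g]
        ann = holders[0].annotation
        if pool_genotypes:
            pooled: dict[JunctionKey, int] = {}
            for gs in holders:
                for key, rec in gs.records.items():
                    pooled[key] = pooled.get(key, 0) + rec.unique_reads
            canonical = _pick_canonical(pooled, ann)
            for gs in holders:
                _partition(gs, canonical)
        else:
            for gs in holders:
                pooled = {k: r.unique_reads for k, r in gs.records.items()}
                _partition(gs, _pick_canonical(pooled, ann))


def _pick_canonical(pooled: Mapping[JunctionKey, int], ann: IntronAnnotation) -> JunctionKey:
    def rank(key: JunctionKey):
        matches_annotated = _junction_ends(key) == (ann.intron_start, ann.intron_end)
        return (-pooled[key], 0 if matches_annotated else 1, key[1], key[2])

    return min(pooled, key=rank)


def _partition(gs: GeneJunctionSet, canonical: JunctionKey) -> None:
    gs.canonical = canonical
    gs.alt3, gs.alt5, gs.neither = [], [], []
    can_donor, can_acceptor = _donor_acceptor(canonical)
    for key in gs.records:
        if key == canonical:
            continue
        donor, acceptor = _donor_acceptor(key)
        if donor == can_donor and acceptor != can_acceptor:
            gs.alt3.append(key)
        elif acceptor == can_acceptor and donor != can_donor:
            gs.alt5.append(key)
        else:
            gs.neither.append(key)
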