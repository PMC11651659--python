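"""Splice-junction tables in the STAR ``SJ.out.tab`` dialect.

A junction table holds one record per splice junction observed in one
sample.  Coordinates are 1-based inclusive positions of the first and
last intron base, as in the SJ dialect.  Strand is encoded ``+``/``-``
with ``.`` for undefined (SJ column 4 codes 1/2/0).

The filtering operations implement the false-positive junction filter
used for alternative splice-site discovery: keep junctions with a
canonical splice-site motif (motif code > 0) supported by more than two
uniquely mapping reads, then require presence in every sample of the
experiment, then pool replicate counts per genotype.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .errors import ConsistencyError, ParseError

# SJ column 4 strand codes
_STRAND_FROM_CODE = {0: ".", 1: "+", 2: "-"}
_CODE_FROM_STRAND = {v: k for k, v in _STRAND_FROM_CODE.items()}

#: key type: (chrom, intron_start, intron_end, strand)
JunctionKey = tuple[str, int, int, str]


@dataclass(frozen=True)
class JunctionRecord:
    """One splice junction in one sample (SJ.out.tab columns 1-9)."""

    chrom: str
    intron_start: int  # 1-based first intron base
    intron_end: int  # 1-based last intron base
    strand: str  # '+', '-' or '.' (undefined)
    motif_code: int  # 0 = non-canonical, 1-6 = canonical dinucleotide pairs
    annotated_flag: int
    unique_reads: int
    multi_reads: int
    max_overhang: int
    line_no: int | None = None

    def __post_init__(self):
        if self.intron_start > self.intron_end:
            raise ParseError(
                f"intron_start {self.intron_start} > intron_end {self.intron_end}",
                line_no=self.line_no,
            )
        if self.unique_reads < 0 or self.multi_reads < 0:
            raise ParseError("negative read count", line_no=self.line_no)
        if not 0 <= self.motif_code <= 6:
            raise ParseError(f"motif_code {self.motif_code} outside 0..6", line_no=self.line_no)

    @property
    def key(self) -> JunctionKey:
        return (self.chrom, self.intron_start, self.intron_end, self.strand)

    @property
    def donor_pos(self) -> int:
        """Genomic position of the first intron base in transcript direction."""
        if self.strand == ".":
            raise ValueError("donor undefined for strand-unknown junction")
        return self.intron_start if self.strand == "+" else self.intron_end

    @property
    def acceptor_pos(self) -> int:
        """Genomic position of the last intron base in transcript direction (the 3'SS)."""
        if self.strand == ".":
            raise ValueError("acceptor undefined for strand-unknown junction")
        return self.intron_end if self.strand == "+" else self.intron_start


@dataclass
class JunctionTable:
    """All junctions of one sample, keyed by (chrom, start, end, strand)."""

    sample_id: str
    genotype: str
    records: dict[JunctionKey, JunctionRecord] = dataclasses.field(default_factory=dict)

    def add(self, rec: JunctionRecord) -> None:
        if rec.key in self.records:
            raise ParseError(
                f"duplicate junction key {rec.key} in sample {self.sample_id}",
                line_no=rec.line_no,
            )
        self.records[rec.key] = rec

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records.values())


def read_sj_table(path, sample_id: str, genotype: str) -> JunctionTable:
    """Parse an SJ.out.tab-dialect file into a :class:`JunctionTable`.

    Raises :class:`ParseError` naming the file and line on a wrong column
    count, non-integer field, coordinate < 1, or duplicate junction key.
    """
    path = Path(path)
    table = JunctionTable(sample_id=sample_id, genotype=genotype)
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"expected 9 tab-separated columns, got {len(fields)}",
                    path=path, line_no=line_no,
                )
            try:
                ints = [int(x) for x in fields[1:]]
            except ValueError as exc:
                raise ParseError(f"non-integer field: {exc}", path=path, line_no=line_no)
            start, end, strand_code, motif, annot, uniq, multi, overhang = ints
            if start < 1 or end < 1:
                raise ParseError("coordinates must be >= 1", path=path, line_no=line_no)
            if strand_code not in _STRAND_FROM_CODE:
                raise ParseError(f"strand code {strand_code} not in 0/1/2", path=path, line_no=line_no)
            rec = JunctionRecord(
                chrom=fields[0], intron_start=start, intron_end=end,
                strand=_STRAND_FROM_CODE[strand_code], motif_code=motif,
                annotated_flag=annot, unique_reads=uniq, multi_reads=multi,
                max_overhang=overhang, line_no=line_no,
            )
            try:
                table.add(rec)
            except ParseError:
                raise ParseError(f"duplicate junction key {rec.key}", path=path, line_no=line_no)
    return table


def write_sj_table(table: JunctionTable, path) -> None:
    """Write a table back out in the 9-column SJ dialect."""
    with open(path, "w") as fh:
        for rec in table:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        rec.chrom, rec.intron_start, rec.intron_end,
                        _CODE_FROM_STRAND[rec.strand], rec.motif_code,
                        rec.annotated_flag, rec.unique_reads, rec.multi_reads,
                        rec.max_overhang,
                    )
                )
                + "\n"
            )


def filter_junctions(
    table: JunctionTable, *, motif_code_min: int = 1, unique_reads_min: int = 3
) -> JunctionTable:
    """Remove likely false-positive junctions.

    Default thresholds keep records with a canonical splice-site motif
    (motif_code > 0) and more than two uniquely mapping reads
    (unique_reads > 2); the unique-read rule subsumes the
    multi-mapper-only rule. Order-stable; the input is not modified.
    """
    out = JunctionTable(sample_id=table.sample_id, genotype=table.genotype)
    for rec in table:
        if rec.motif_code >= motif_code_min and rec.unique_reads >= unique_reads_min:
            out.records[rec.key] = rec
    return out


def intersect_across_samples(tables: Sequence[JunctionTable]) -> list[JunctionTable]:
    """Keep only junction keys present in every sample.

    Implements the presence-in-all-samples requirement applied before
    replicate pooling, so every retained junction has a defined count in
    both genotypes.
    """
    if not tables:
        raise ValueError("need at least one table")
    common = set(tables[0].records)
    for t in tables[1:]:
        common &= set(t.records)
    out = []
    for t in tables:
        nt = JunctionTable(sample_id=t.sample_id, genotype=t.genotype)
        nt.records = {k: r for k, r in t.records.items() if k in common}
        out.append(nt)
    return out


def merge_replicates(tables: Sequence[JunctionTable]) -> JunctionTable:
    """Pool replicate tables of one genotype by summing read counts per junction.

    unique_reads and multi_reads are summed; the remaining fields are taken
    from the first replicate and must agree across replicates (a conflicting
    strand or motif_code raises :class:`ConsistencyError`).
    """
    if not tables:
        raise ValueError("need at least one table")
    genotypes = {t.genotype for t in tables}
    if len(genotypes) != 1:
        raise ConsistencyError(f"cannot merge across genotypes: {sorted(genotypes)}")
    genotype = tables[0].genotype
    merged = JunctionTable(sample_id=f"{genotype}_merged", genotype=genotype)
    for t in tables:
        for rec in t:
            prev = merged.records.get(rec.key)
            if prev is None:
                merged.records[rec.key] = rec
            else:
                if (prev.strand, prev.motif_code) != (rec.strand, rec.motif_code):
                    raise ConsistencyError(
                        f"junction {rec.key}: strand/motif_code differ between replicates"
                    )
                merged.records[rec.key] = dataclasses.replace(
                    prev,
                    unique_reads=prev.unique_reads + rec.unique_reads,
                    multi_reads=prev.multi_reads + rec.multi_reads,
                )
    return merged


def group_by_genotype(tables: Iterable[JunctionTable]) -> dict[str, list[JunctionTable]]:
    """Bucket sample tables by genotype label, preserving order."""
    groups: dict[str, list[JunctionTable]] = {}
    for t in tables:
        groups.setdefault(t.genotype, []).append(t)
    return groups
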