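"""Synthetic junction-count data with planted alternative 3' splice sites.

The generator emulates a two-genotype (wild type vs splicing-factor
mutant), two-replicate bulk RNA-seq experiment over single-intron genes
on a toy chromosome.  Each gene carries one canonical intron (GT donor,
YAG acceptor, annotated branch point) and zero or more alternative
acceptors at signed transcript-direction offsets from the canonical
3'SS, each with a planted wild-type usage fraction, a mutant fold change
of its FAnS value (alternative/canonical usage ratio), and a planted
3'SS motif class.  Per-sample junction read counts are drawn from a
Poisson (default) or negative-binomial model at mean
``expression_mean x usage`` and emitted in the SJ.out.tab dialect, so
the entire downstream pipeline runs from files identical in shape to a
real experiment while every event's FAnS, ratio, direction, distances
and motif are known exactly.

The ``mirror_*`` helpers reverse-complement a whole simulated dataset
(genome, annotation, junction tables) for strand-symmetry validation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import reverse_complement

from .annotation import IntronAnnotation, write_intron_table
from .errors import ConfigurationError
from .fans import classify_direction_and_distance
from .junctions import JunctionRecord, JunctionTable
from .motifs import CLASS_REPRESENTATIVE, classify_3ss_motif

_DNA = str.maketrans("U", "T")


@dataclass(frozen=True)
class AltSiteSpec:
    """One planted alternative 3'SS.

    ``delta_3ss`` is the signed transcript-direction offset from the
    canonical acceptor (negative = upstream).  ``wt_usage`` is the
    isoform's usage fraction in the wild type; ``mut_fold_change``
    multiplies the site's FAnS value (usage over canonical usage) in the
    mutant.  ``motif`` optionally overrides the class-representative RNA
    trinucleotide.
    """

    delta_3ss: int
    wt_usage: float
    mut_fold_change: float = 1.0
    motif_class: str = "YAG"
    motif: str | None = None

    def resolved_motif(self) -> str:
        m = self.motif if self.motif is not None else CLASS_REPRESENTATIVE[self.motif_class]
        got = classify_3ss_motif(m)
        if got != self.motif_class:
            raise ConfigurationError(
                f"motif {m!r} classifies as {got}, not {self.motif_class}"
            )
        return m


@dataclass(frozen=True)
class SimulationConfig:
    """Planted truth and noise model for one simulated experiment.

    Defaults mirror the study layout: two genotypes with two replicates
    each, single-intron genes on one chromosome, half on each strand,
    canonical-isoform depth of 1000 junction reads per replicate, and
    one upstream alternative acceptor per gene 20 nt from the canonical
    site at 2% wild-type usage, upregulated 5-fold in the mutant.
    """

    n_genes: int = 100
    chrom_name: str = "chrSim"
    minus_fraction: float = 0.5
    exon_len: int = 300
    intron_len: int = 120
    bp_offset_from_3ss: int = 30
    alt_sites: Sequence[Sequence[AltSiteSpec]] | Sequence[AltSiteSpec] = (
        AltSiteSpec(delta_3ss=-20, wt_usage=0.02, mut_fold_change=5.0),
    )
    rpg_fraction: float = 0.3
    expression_mean: float = 1000.0
    replicates_per_genotype: int = 2
    genotypes: tuple[str, str] = ("wt", "mut")
    noise_model: str = "poisson"
    nb_dispersion: float = 0.1
    non_ag_motif_code: int = 0
    canonical_motif: str = "UAG"
    intergenic_gap: int = 100
    seed: int = 0

    def per_gene_sites(self) -> list[tuple[AltSiteSpec, ...]]:
        """Alt-site specs per gene; a flat spec list is applied to every gene."""
        spec = self.alt_sites
        if len(spec) == 0 or isinstance(spec[0], AltSiteSpec):
            return [tuple(spec)] * self.n_genes
        if len(spec) != self.n_genes:
            raise ConfigurationError(
                f"alt_sites lists {len(spec)} genes but n_genes={self.n_genes}"
            )
        return [tuple(s) for s in spec]

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if self.bp_offset_from_3ss < 1:
            raise ConfigurationError("bp_offset_from_3ss must be >= 1")
        if self.bp_offset_from_3ss > self.intron_len - 3:
            raise ConfigurationError("branch point would leave the intron")
        if self.noise_model not in {"poisson", "negative_binomial"}:
            raise ConfigurationError(f"unknown noise_model {self.noise_model!r}")
        if not 0 <= self.minus_fraction <= 1:
            raise ConfigurationError("minus_fraction must lie in [0,1]")
        for gi, sites in enumerate(self.per_gene_sites()):
            total = sum(s.wt_usage for s in sites)
            if total >= 1:
                raise ConfigurationError(
                    f"gene {gi}: wild-type alternative usage sums to {total} >= 1"
                )
            for s in sites:
                if s.wt_usage < 0 or s.mut_fold_change <= 0:
                    raise ConfigurationError(f"gene {gi}: invalid alt-site usage/fold")
                # acceptor and its motif must stay inside the gene body
                if s.delta_3ss == 0:
                    raise ConfigurationError(f"gene {gi}: delta_3ss must be nonzero")
                if s.delta_3ss < 0 and -s.delta_3ss > self.intron_len - 5:
                    raise ConfigurationError(
                        f"gene {gi}: upstream acceptor at {s.delta_3ss} leaves the intron"
                    )
                if s.delta_3ss > 0 and s.delta_3ss > self.exon_len - 3:
                    raise ConfigurationError(
                        f"gene {gi}: downstream acceptor at {s.delta_3ss} leaves the gene"
                    )


@dataclass
class PlantedTruth:
    """Ground truth of a simulation: per-gene canonical usage and per-site
    FAnS/geometry/motif, as data frames keyed by gene_id."""

    genes: pd.DataFrame
    sites: pd.DataFrame


def _gene_len(cfg: SimulationConfig) -> int:
    return 2 * cfg.exon_len + cfg.intron_len


def build_annotation(config: SimulationConfig) -> tuple[list[IntronAnnotation], PlantedTruth]:
    """Lay out genes on the toy chromosome and derive the planted truth.

    Deterministic given the config seed: strand and gene-class draws use
    fixed sub-streams of the master seed.
    """
    config.validate()
    n = config.n_genes
    strands = np.where(
        np.random.default_rng([config.seed, 101]).random(n) < config.minus_fraction, "-", "+"
    )
    classes = np.where(
        np.random.default_rng([config.seed, 102]).random(n) < config.rpg_fraction,
        "RPG", "non-RPG",
    )
    annotations: list[IntronAnnotation] = []
    gene_rows, site_rows = [], []
    per_gene = config.per_gene_sites()
    for i in range(n):
        gene_id = f"SYN{i:04d}"
        strand = str(strands[i])
        gene_start = 1 + config.intergenic_gap + i * (_gene_len(config) + config.intergenic_gap)
        istart = gene_start + config.exon_len
        iend = istart + config.intron_len - 1
        if strand == "+":
            acceptor = iend
            bp = iend - config.bp_offset_from_3ss
        else:
            acceptor = istart
            bp = istart + config.bp_offset_from_3ss
        ann = IntronAnnotation(
            gene_id=gene_id, gene_class=str(classes[i]), chrom=config.chrom_name,
            strand=strand, intron_index=1, intron_start=istart, intron_end=iend,
            bp_pos=bp,
        )
        annotations.append(ann)

        sites = per_gene[i]
        canon_wt = 1.0 - sum(s.wt_usage for s in sites)
        fans_wt = [s.wt_usage / canon_wt for s in sites]
        fans_mut = [f * s.mut_fold_change for f, s in zip(fans_wt, sites)]
        canon_mut = 1.0 / (1.0 + sum(fans_mut))
        gene_rows.append(
            {
                "gene_id": gene_id, "gene_class": str(classes[i]), "strand": strand,
                "gene_start": gene_start, "gene_end": gene_start + _gene_len(config) - 1,
                "usage_canonical_wt": canon_wt, "usage_canonical_mut": canon_mut,
            }
        )
        for si, s in enumerate(sites):
            alt_acceptor = acceptor + s.delta_3ss if strand == "+" else acceptor - s.delta_3ss
            jstart = istart if strand == "+" else alt_acceptor
            jend = alt_acceptor if strand == "+" else iend
            direction, delta, bp_distance, upstream_of_bp = classify_direction_and_distance(
                strand, acceptor, alt_acceptor, bp
            )
            motif = s.resolved_motif()
            site_rows.append(
                {
                    "gene_id": gene_id, "site_index": si, "strand": strand,
                    "junction_start": jstart, "junction_end": jend,
                    "acceptor_pos": alt_acceptor,
                    "delta_3ss": delta, "direction": direction,
                    "bp_distance": bp_distance, "upstream_of_bp": upstream_of_bp,
                    "motif": motif, "motif_class": s.motif_class,
                    "usage_wt": s.wt_usage,
                    "usage_mut": fans_mut[si] * canon_mut,
                    "fans_wt": fans_wt[si], "fans_mut": fans_mut[si],
                    "fans_ratio": s.mut_fold_change,
                    "log10_fans_ratio": float(np.log10(s.mut_fold_change)),
                }
            )
    truth = PlantedTruth(genes=pd.DataFrame(gene_rows), sites=pd.DataFrame(site_rows))
    return annotations, truth


def build_genome(
    annotations: Sequence[IntronAnnotation], truth: PlantedTruth, config: SimulationConfig
) -> dict[str, str]:
    """Random background sequence with splice elements planted.

    Plants GT at every donor, A at every branch point, the canonical YAG
    motif at every canonical acceptor and each site's planted
    trinucleotide at its alternative acceptor, all in transcript
    orientation (reverse-complemented on the minus strand).  Two planted
    elements writing conflicting letters to one base is a generation
    error.
    """
    last = max(a.intron_end for a in annotations)
    length = last + config.exon_len + config.intergenic_gap
    rng = np.random.default_rng([config.seed, 103])
    seq = rng.choice(list("ACGT"), size=length)
    planted: dict[int, str] = {}

    def plant(pos1: int, letters: str, what: str) -> None:
        for off, ch in enumerate(letters):
            p = pos1 + off
            if not 1 <= p <= length:
                raise ConfigurationError(f"{what}: position {p} outside chromosome")
            prev = planted.get(p)
            if prev is not None and prev != ch:
                raise ConfigurationError(
                    f"{what}: conflicting letters {prev!r} vs {ch!r} at position {p}"
                )
            planted[p] = ch
            seq[p - 1] = ch

    def plant_tx(end_pos: int, rna: str, strand: str, what: str) -> None:
        """Plant a transcript-orientation motif whose last base sits at end_pos."""
        dna = rna.translate(_DNA)
        if strand == "+":
            plant(end_pos - len(dna) + 1, dna, what)
        else:
            plant(end_pos, reverse_complement(dna), what)

    sites_by_gene: dict[str, list] = {}
    for row in truth.sites.itertuples(index=False):
        sites_by_gene.setdefault(row.gene_id, []).append(row)
    for ann in annotations:
        if ann.strand == "+":
            plant(ann.intron_start, "GT", f"{ann.gene_id} donor")
            plant(ann.bp_pos, "A", f"{ann.gene_id} branch point")
        else:
            plant(ann.intron_end - 1, "AC", f"{ann.gene_id} donor")
            plant(ann.bp_pos, "T", f"{ann.gene_id} branch point")
        plant_tx(ann.acceptor_pos, config.canonical_motif, ann.strand,
                 f"{ann.gene_id} canonical 3'SS")
        for row in sites_by_gene.get(ann.gene_id, []):
            plant_tx(int(row.acceptor_pos), row.motif, ann.strand,
                     f"{ann.gene_id} alt site {row.site_index}")
    return {config.chrom_name: "".join(seq)}


def write_genome_fasta(genome: Mapping[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _draw_counts(rng: np.random.Generator, mean: float, size: int, config: SimulationConfig):
    if mean == 0:
        return np.zeros(size, dtype=int)
    if config.noise_model == "poisson":
        return rng.poisson(mean, size=size)
    # NB with var = mean + dispersion * mean^2
    r = 1.0 / config.nb_dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


def simulate_junction_counts(
    annotations: Sequence[IntronAnnotation], truth: PlantedTruth, config: SimulationConfig
) -> dict[tuple[str, int], JunctionTable]:
    """Draw per-sample junction tables, keyed by (genotype, replicate).

    Each sample uses an RNG stream derived from the master seed and its
    (genotype, replicate) indices, so adding replicates never perturbs
    existing samples.
    """
    config.validate()
    genes = truth.genes.set_index("gene_id")
    sites_by_gene: dict[str, list] = {}
    for row in truth.sites.itertuples(index=False):
        sites_by_gene.setdefault(row.gene_id, []).append(row)

    tables: dict[tuple[str, int], JunctionTable] = {}
    for g_idx, genotype in enumerate(config.genotypes):
        suffix = "wt" if g_idx == 0 else "mut"
        for rep in range(1, config.replicates_per_genotype + 1):
            rng = np.random.default_rng([config.seed, 7, g_idx, rep])
            table = JunctionTable(sample_id=f"{genotype}_rep{rep}", genotype=genotype)
            for ann in annotations:
                usage_canon = genes.loc[ann.gene_id, f"usage_canonical_{suffix}"]
                count = int(_draw_counts(rng, config.expression_mean * usage_canon, 1, config)[0])
                table.add(
                    JunctionRecord(
                        chrom=ann.chrom, intron_start=ann.intron_start,
                        intron_end=ann.intron_end, strand=ann.strand,
                        motif_code=1, annotated_flag=1, unique_reads=count,
                        multi_reads=0, max_overhang=38,
                    )
                )
                for row in sites_by_gene.get(ann.gene_id, []):
                    usage = row.usage_wt if suffix == "wt" else row.usage_mut
                    count = int(_draw_counts(rng, config.expression_mean * usage, 1, config)[0])
                    code = 1 if row.motif.endswith("AG") else config.non_ag_motif_code
                    table.add(
                        JunctionRecord(
                            chrom=ann.chrom, intron_start=int(row.junction_start),
                            intron_end=int(row.junction_end), strand=ann.strand,
                            motif_code=code, annotated_flag=0, unique_reads=count,
                            multi_reads=0, max_overhang=38,
                        )
                    )
            tables[(genotype, rep)] = table
    return tables


def write_sj_tables(tables: Mapping[tuple[str, int], JunctionTable], directory) -> Path:
    """Write one SJ.out.tab file per sample plus a manifest TSV; returns the
    manifest path."""
    from .junctions import write_sj_table

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for (genotype, rep), table in tables.items():
        fname = f"{genotype}_rep{rep}.SJ.out.tab"
        write_sj_table(table, directory / fname)
        rows.append({"sample_id": table.sample_id, "genotype": genotype, "path": fname})
    manifest = directory / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    return manifest


def simulate_dataset(config: SimulationConfig, directory) -> dict[str, Path]:
    """Run the full generator and write annotation, truth, genome and SJ tables."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    annotations, truth = build_annotation(config)
    genome = build_genome(annotations, truth, config)
    paths = {
        "annotation": directory / "introns.tsv",
        "genome": directory / "genome.fa",
        "truth_sites": directory / "truth_sites.tsv",
        "truth_genes": directory / "truth_genes.tsv",
    }
    write_intron_table(annotations, paths["annotation"])
    write_genome_fasta(genome, paths["genome"])
    truth.sites.to_csv(paths["truth_sites"], sep="\t", index=False)
    truth.genes.to_csv(paths["truth_genes"], sep="\t", index=False)
    tables = simulate_junction_counts(annotations, truth, config)
    paths["manifest"] = write_sj_tables(tables, directory)
    return paths


# ---------------------------------------------------------------------------
# strand-mirror helpers (validation only)

def mirror_position(pos: int, length: int) -> int:
    return length - pos + 1


def mirror_genome(genome: Mapping[str, str]) -> dict[str, str]:
    return {c: reverse_complement(s) for c, s in genome.items()}


def mirror_annotation(
    annotations: Sequence[IntronAnnotation], lengths: Mapping[str, int]
) -> list[IntronAnnotation]:
    out = []
    for a in annotations:
        L = lengths[a.chrom]
        out.append(
            dataclasses.replace(
                a,
                strand="-" if a.strand == "+" else "+",
                intron_start=mirror_position(a.intron_end, L),
                intron_end=mirror_position(a.intron_start, L),
                bp_pos=mirror_position(a.bp_pos, L),
            )
        )
    return out


def mirror_table(table: JunctionTable, lengths: Mapping[str, int]) -> JunctionTable:
    out = JunctionTable(sample_id=table.sample_id, genotype=table.genotype)
    for rec in table:
        L = lengths[rec.chrom]
        out.add(
            dataclasses.replace(
                rec,
                strand={"+": "-", "-": "+", ".": "."}[rec.strand],
                intron_start=mirror_position(rec.intron_end, L),
                intron_end=mirror_position(rec.intron_start, L),
            )
        )
    return out
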