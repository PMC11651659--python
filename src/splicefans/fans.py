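"""FAnS statistic, PSI, and strand-aware alternative-3'SS classification.

FAnS (fraction of annotated splicing) for an alternative junction is its
unique-read count divided by the canonical junction's count in the same
sample, so it is invariant to expression changes; the between-genotype
ratio FAnS(mut)/FAnS(wt) measures up/down-regulation of the alternative
site.  Undefined values (zero denominator) are reported as NaN with a
flag column, never as exceptions, and excluded from ratio summaries.

Distances are signed in transcript direction: delta_3ss is alternative
minus canonical 3'SS (negative = upstream, branch-point-proximal side);
bp_distance is the alternative acceptor minus the annotated branch-point
adenosine, so bp_distance <= 0 marks sites at or upstream of the BP.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneJunctionSet, IntronAnnotation, _donor_acceptor
from .errors import ConfigurationError, InternalError
from . import motifs as _motifs

EVENT_COLUMNS = [
    "gene_id", "gene_class", "intron_index", "chrom", "strand", "shared_side",
    "junction_start", "junction_end", "donor_pos", "acceptor_pos",
    "canonical_acceptor",
    "count_canonical_wt", "count_alt_wt", "count_canonical_mut", "count_alt_mut",
    "fans_wt", "fans_mut", "fans_ratio", "log10_fans_ratio", "ratio_defined",
    "direction", "delta_3ss", "bp_distance", "upstream_of_bp",
    "last3", "motif_class",
    "psi_wt", "psi_mut", "delta_psi", "delta_psi_ge_10",
]


def compute_fans(count_alt: float, count_canonical: float) -> float:
    """Alternative-junction reads over canonical-junction reads; NaN if the
    canonical count is zero (undefined, flagged downstream)."""
    if count_alt < 0 or count_canonical < 0:
        raise ValueError("counts must be non-negative")
    if count_canonical == 0:
        return math.nan
    return count_alt / count_canonical


def compute_fans_ratio(fans_mut: float, fans_wt: float) -> tuple[float, float]:
    """Return (FAnS ratio, log10 ratio) for mutant over wild type.

    NaN in either input, or a zero wild-type FAnS, yields (NaN, NaN).
    """
    if math.isnan(fans_mut) or math.isnan(fans_wt) or fans_wt == 0:
        return math.nan, math.nan
    ratio = fans_mut / fans_wt
    return ratio, (math.log10(ratio) if ratio > 0 else -math.inf)


def compute_psi(count_canonical: float, counts_alt: Sequence[float]) -> np.ndarray:
    """Percent-spliced-in per isoform: each junction's reads over the event total.

    Returns an array ``[psi_canonical, psi_alt_1, ...]`` summing to 1; all
    NaN when the total is zero.
    """
    counts = np.asarray([count_canonical, *counts_alt], dtype=float)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    total = counts.sum()
    if total == 0:
        return np.full_like(counts, np.nan)
    return counts / total


def classify_direction_and_distance(
    strand: str,
    canonical_acceptor: int,
    alt_acceptor: int,
    bp_pos: int,
) -> tuple[str, int, int, bool]:
    """Classify an alternative 3'SS relative to the canonical site and BP.

    Returns (direction, delta_3ss, bp_distance, upstream_of_bp) with all
    distances signed in transcript direction.
    """
    if strand == "+":
        delta = alt_acceptor - canonical_acceptor
        bp_distance = alt_acceptor - bp_pos
    elif strand == "-":
        delta = canonical_acceptor - alt_acceptor
        bp_distance = bp_pos - alt_acceptor
    else:
        raise ValueError(f"unknown strand {strand!r}")
    if delta == 0:
        raise InternalError("alternative acceptor equals canonical acceptor")
    direction = "upstream" if delta < 0 else "downstream"
    return direction, delta, bp_distance, bp_distance <= 0


def build_event_table(
    assignments: Mapping[str, dict[tuple[str, int], GeneJunctionSet]],
    *,
    wt: str,
    mut: str,
    genome=None,
    with_motifs: bool | None = None,
    pseudocount: float = 0.0,
    delta_psi_threshold: float = 0.10,
) -> pd.DataFrame:
    """Build the per-alternative-junction event table for one wt/mut comparison.

    One row per (intron, alternative junction, shared side).  Requires
    canonical sites to have been called.  Motif columns (last three
    intron nucleotides and motif class) are filled for alternative-3'SS
    events when a genome is available; requesting them without a genome
    is a configuration error.
    """
    if with_motifs is None:
        with_motifs = genome is not None
    if with_motifs and genome is None:
        raise ConfigurationError("motif columns requested but no genome supplied")
    for label in (wt, mut):
        if label not in assignments:
            raise ConfigurationError(f"genotype {label!r} absent from assignments")

    rows = []
    idents = [i for i in assignments[wt] if i in assignments[mut]]
    for ident in idents:
        gs_wt = assignments[wt][ident]
        gs_mut = assignments[mut][ident]
        ann = gs_wt.annotation
        canonical = gs_wt.canonical
        if canonical is None or canonical != gs_mut.canonical:
            raise InternalError(f"canonical site not called consistently for {ident}")
        c_wt = gs_wt.count(canonical) + pseudocount
        c_mut = gs_mut.count(canonical) + pseudocount

        for side, keys in (("alt_3ss", gs_wt.alt3), ("alt_5ss", gs_wt.alt5)):
            side_alt_wt = [gs_wt.count(k) + pseudocount for k in keys]
            side_alt_mut = [gs_mut.count(k) + pseudocount for k in keys]
            psi_wt_all = compute_psi(c_wt, side_alt_wt)
            psi_mut_all = compute_psi(c_mut, side_alt_mut)
            for i, key in enumerate(keys):
                rows.append(
                    _event_row(
                        ann, key, side,
                        c_wt, side_alt_wt[i], c_mut, side_alt_mut[i],
                        psi_wt_all[1 + i], psi_mut_all[1 + i],
                        genome if with_motifs else None,
                        delta_psi_threshold,
                    )
                )
    df = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    return df


def _event_row(
    ann: IntronAnnotation, key, side,
    c_wt, a_wt, c_mut, a_mut, psi_wt, psi_mut,
    genome, delta_psi_threshold,
):
    donor, acceptor = _donor_acceptor(key)
    fans_wt = compute_fans(a_wt, c_wt)
    fans_mut = compute_fans(a_mut, c_mut)
    ratio, log10_ratio = compute_fans_ratio(fans_mut, fans_wt)
    direction = delta = bp_distance = upstream_of_bp = None
    last3 = motif_class = None
    if side == "alt_3ss":
        direction, delta, bp_distance, upstream_of_bp = classify_direction_and_distance(
            ann.strand, ann.acceptor_pos, acceptor, ann.bp_pos
        )
        if genome is not None:
            last3 = _motifs.extract_3ss_sequence(
                genome, ann.chrom, acceptor, ann.strand, window=(-2, 0)
            )
            motif_class = _motifs.classify_3ss_motif(last3)
    delta_psi = psi_mut - psi_wt
    return {
        "gene_id": ann.gene_id, "gene_class": ann.gene_class,
        "intron_index": ann.intron_index, "chrom": ann.chrom, "strand": ann.strand,
        "shared_side": side,
        "junction_start": key[1], "junction_end": key[2],
        "donor_pos": donor, "acceptor_pos": acceptor,
        "canonical_acceptor": ann.acceptor_pos,
        "count_canonical_wt": c_wt, "count_alt_wt": a_wt,
        "count_canonical_mut": c_mut, "count_alt_mut": a_mut,
        "fans_wt": fans_wt, "fans_mut": fans_mut,
        "fans_ratio": ratio, "log10_fans_ratio": log10_ratio,
        "ratio_defined": not (math.isnan(ratio) if isinstance(ratio, float) else False),
        "direction": direction, "delta_3ss": delta,
        "bp_distance": bp_distance, "upstream_of_bp": upstream_of_bp,
        "last3": last3, "motif_class": motif_class,
        "psi_wt": psi_wt, "psi_mut": psi_mut, "delta_psi": delta_psi,
        "delta_psi_ge_10": bool(abs(delta_psi) >= delta_psi_threshold)
        if not math.isnan(delta_psi) else False,
    }


def write_event_table(events: pd.DataFrame, path) -> None:
    """Write the event table as TSV with ratios printed to 6 significant digits."""
    events.to_csv(path, sep="\t", index=False, float_format="%.6g")


def summarize_by_bins(
    events: pd.DataFrame, column: str, edges: Sequence[float]
) -> pd.DataFrame:
    """Median/quartile summary of log10 FAnS ratios binned on a distance column.

    Only alternative-3'SS events with a defined ratio contribute.
    """
    sub = events[(events["shared_side"] == "alt_3ss") & events["ratio_defined"]].copy()
    sub["log10_fans_ratio"] = pd.to_numeric(sub["log10_fans_ratio"])
    sub[column] = pd.to_numeric(sub[column])
    sub = sub[np.isfinite(sub["log10_fans_ratio"])]
    sub["bin"] = pd.cut(sub[column], bins=list(edges))
    grouped = sub.groupby("bin", observed=False)["log10_fans_ratio"]
    out = grouped.agg(n="count", median="median",
                      q1=lambda s: s.quantile(0.25), q3=lambda s: s.quantile(0.75))
    return out.reset_index()
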