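"""3'SS sequence extraction, motif classification and position-frequency matrices.

The yeast 3'SS consensus is YAG (Y = C/U), the last three intron
nucleotides.  Non-consensus acceptors are grouped into NAG (non-Y at -3,
e.g. the cryptic GAG class), HAU (H = A/C/U) and BG (B = C/G/U) motifs,
with everything else labeled OTHER.  Classification is total: every RNA
trinucleotide maps to exactly one label, with AG-ending sites always
judged at position -3 first.

Sequences are reported in transcript orientation in the RNA alphabet,
over a window anchored at the acceptor (offset 0 = last intron base);
position-frequency matrices over such windows feed sequence logos.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import reverse_complement

from .errors import SpliceFansError

RNA_BASES = ("A", "C", "G", "U")
MOTIF_CLASSES = ("YAG", "NAG_nonY", "HAU", "BG", "OTHER")

#: representative trinucleotide planted by the simulator for each class
CLASS_REPRESENTATIVE = {
    "YAG": "CAG",
    "NAG_nonY": "GAG",
    "HAU": "AAU",
    "BG": "UGG",
    "OTHER": "GAC",
}


def classify_3ss_motif(last3: str) -> str:
    """Classify the last three intron nucleotides of a 3' splice site.

    Precedence: AG-ending sites are YAG (Y = C/U at -3) or NAG_nonY;
    otherwise G-ending sites with B = C/G/U at -2 are BG; otherwise
    AU-ending sites with H = A/C/U at -3 are HAU; else OTHER.
    """
    s = last3.upper()
    if len(s) != 3 or any(ch not in RNA_BASES for ch in s):
        raise ValueError(f"expected an RNA trinucleotide over ACGU, got {last3!r}")
    if s[1:] == "AG":
        return "YAG" if s[0] in "CU" else "NAG_nonY"
    if s[2] == "G" and s[1] in "CGU":
        return "BG"
    if s[1:] == "AU" and s[0] in "ACU":
        return "HAU"
    return "OTHER"


def _fetch_plus(genome, chrom: str, start: int, end: int) -> str:
    """Plus-strand slice [start, end] (1-based inclusive) from a FASTA handle
    (pyfaidx.Fasta) or a plain mapping of chromosome name to sequence string."""
    try:
        seq = genome[chrom]
    except KeyError:
        raise SpliceFansError(f"chromosome {chrom!r} not in genome")
    length = len(seq)
    if start < 1 or end > length:
        raise SpliceFansError(
            f"window [{start},{end}] outside {chrom} (length {length})"
        )
    if isinstance(seq, str):
        return seq[start - 1 : end].upper()
    return str(seq[start - 1 : end]).upper()


def extract_3ss_sequence(
    genome, chrom: str, acceptor_pos: int, strand: str, window: tuple[int, int] = (-9, 2)
) -> str:
    """Transcript-orientation RNA sequence around a 3'SS.

    ``window`` gives inclusive offsets relative to the acceptor, with
    offset 0 the last intron base; minus-strand sites are
    reverse-complemented.  DNA T is transliterated to U.
    """
    lo, hi = window
    if lo > hi:
        raise ValueError("window start must not exceed window end")
    if strand == "+":
        raw = _fetch_plus(genome, chrom, acceptor_pos + lo, acceptor_pos + hi)
    elif strand == "-":
        raw = _fetch_plus(genome, chrom, acceptor_pos - hi, acceptor_pos - lo)
        raw = reverse_complement(raw)
    else:
        raise ValueError(f"unknown strand {strand!r}")
    return raw.replace("T", "U")


@dataclass
class Pfm:
    """Position-frequency matrix over an acceptor-anchored window.

    ``freq`` is indexed by offset (0 = last intron base) with columns
    A/C/G/U; each row sums to 1 over the bases observed at that offset.
    """

    freq: pd.DataFrame
    n_sequences: int

    def to_tsv(self, path) -> None:
        out = self.freq.copy()
        out.index.name = "offset"
        out.to_csv(path, sep="\t", float_format="%.6g")


def build_pfm(sequences: Sequence[str], offsets: Iterable[int] | None = None) -> Pfm:
    """Per-offset base frequencies over equal-length RNA strings.

    Ambiguous letters (``N``) are excluded from that column's denominator.
    """
    if not sequences:
        raise ValueError("need at least one sequence")
    width = len(sequences[0])
    if any(len(s) != width for s in sequences):
        raise ValueError("sequences must all have the window length")
    if offsets is None:
        offsets = range(-(width - 1), 1)
    offsets = list(offsets)
    if len(offsets) != width:
        raise ValueError(f"{len(offsets)} offsets for width-{width} sequences")
    counts = np.zeros((width, 4), dtype=float)
    base_idx = {b: i for i, b in enumerate(RNA_BASES)}
    for s in sequences:
        for col, ch in enumerate(s.upper()):
            i = base_idx.get(ch)
            if i is not None:
                counts[col, i] += 1
    totals = counts.sum(axis=1, keepdims=True)
    totals[totals == 0] = np.nan
    freq = pd.DataFrame(counts / totals, index=offsets, columns=list(RNA_BASES))
    return Pfm(freq=freq, n_sequences=len(sequences))


def logos_by_direction(
    events: pd.DataFrame, genome, window: tuple[int, int] = (-9, 2)
) -> dict[str, Pfm]:
    """PFMs for upstream and downstream alternative 3'SS plus the canonical
    sites of the same genes, restricted to events with FAnS > 0 in the mutant."""
    sub = events[
        (events["shared_side"] == "alt_3ss") & (events["fans_mut"] > 0)
    ]
    offsets = list(range(window[0], window[1] + 1))
    out: dict[str, Pfm] = {}
    for direction in ("upstream", "downstream"):
        grp = sub[sub["direction"] == direction]
        seqs = [
            extract_3ss_sequence(genome, r.chrom, int(r.acceptor_pos), r.strand, window)
            for r in grp.itertuples(index=False)
        ]
        if seqs:
            out[direction] = build_pfm(seqs, offsets)
    canon = sub.drop_duplicates(subset=["gene_id", "intron_index"])
    seqs = [
        extract_3ss_sequence(genome, r.chrom, int(r.canonical_acceptor), r.strand, window)
        for r in canon.itertuples(index=False)
    ]
    if seqs:
        out["canonical"] = build_pfm(seqs, offsets)
    return out


def stratify_ratio_by_motif(events: pd.DataFrame) -> pd.DataFrame:
    """Per-motif-class summary (n, median, quartiles) of log10 FAnS ratios.

    Restricted to alternative-3'SS events with FAnS > 0 in both genotypes
    and a defined ratio; empty classes are reported with n = 0.
    """
    sub = events[
        (events["shared_side"] == "alt_3ss")
        & (events["fans_wt"] > 0)
        & (events["fans_mut"] > 0)
        & events["ratio_defined"]
    ]
    rows = []
    for label in MOTIF_CLASSES:
        vals = sub.loc[sub["motif_class"] == label, "log10_fans_ratio"]
        rows.append(
            {
                "motif_class": label,
                "n": int(len(vals)),
                "median": vals.median() if len(vals) else np.nan,
                "q1": vals.quantile(0.25) if len(vals) else np.nan,
                "q3": vals.quantile(0.75) if len(vals) else np.nan,
            }
        )
    return pd.DataFrame(rows)
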