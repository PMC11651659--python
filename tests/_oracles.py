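"""Independent brute-force oracles used only by the test suite."""

import math


def transcript_walk_classify(strand, intron_start, intron_end, bp_pos, alt_acceptor):
    """Classify an alternative acceptor by literally walking the transcript
    base by base and differencing walk indices (independent of the
    arithmetic formulas in the package)."""
    lo = min(intron_start, intron_end, bp_pos, alt_acceptor) - 1
    hi = max(intron_start, intron_end, bp_pos, alt_acceptor) + 1
    if strand == "+":
        walk = list(range(lo, hi + 1))
    else:
        walk = list(range(hi, lo - 1, -1))
    index = {pos: i for i, pos in enumerate(walk)}
    canonical_acceptor = intron_end if strand == "+" else intron_start
    delta = index[alt_acceptor] - index[canonical_acceptor]
    bp_distance = index[alt_acceptor] - index[bp_pos]
    direction = "upstream" if delta < 0 else "downstream"
    return direction, delta, bp_distance, bp_distance <= 0


def welch_t_test(a, b):
    """Textbook Welch t statistic, Welch-Satterthwaite df and two-sided p."""
    from scipy.stats import t as t_dist

    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * (1 - t_dist.cdf(abs(t), df))
    return t, df, p


def brute_force_motif_class(last3):
    """Exhaustive re-statement of the motif classes as set membership,
    written independently of the package's precedence chain."""
    y, h, b = set("CU"), set("ACU"), set("CGU")
    m3, m2, m1 = last3[0], last3[1], last3[2]
    if (m2, m1) == ("A", "G"):
        return "YAG" if m3 in y else "NAG_nonY"
    if m1 == "G" and m2 in b:
        return "BG"
    if (m2, m1) == ("A", "U") and m3 in h:
        return "HAU"
    return "OTHER"
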