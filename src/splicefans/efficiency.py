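"""Second-step (exon ligation) splicing efficiency from band intensities.

Efficiency is mRNA / (mRNA + lariat intermediate) per replicate; groups
are summarized as mean +/- SD and compared between genotypes per
reporter with an unpaired two-sided Welch t-test.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

INTENSITY_COLUMNS = [
    "reporter_id", "genotype", "replicate", "bp_3ss_distance",
    "intensity_mrna", "intensity_lariat",
]


def read_intensity_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in INTENSITY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"intensity table missing columns {missing}")
    return df


def second_step_efficiency(intensity_mrna: float, intensity_lariat: float) -> float:
    """mRNA band intensity over mRNA + lariat intermediate, in [0, 1].

    Scale-invariant in the common intensity units; NaN (undefined) when
    both intensities are zero.
    """
    if intensity_mrna < 0 or intensity_lariat < 0:
        raise ValueError("intensities must be non-negative")
    total = intensity_mrna + intensity_lariat
    if total == 0:
        return math.nan
    return intensity_mrna / total


def add_efficiency(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    out["efficiency"] = [
        second_step_efficiency(m, l)
        for m, l in zip(out["intensity_mrna"], out["intensity_lariat"])
    ]
    return out


def summarize_by_distance(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group means and Welch comparisons across the BP-3'SS distance series.

    Returns (per-(reporter, genotype) summary, per-reporter two-genotype
    comparison).  Groups with fewer than two replicates are skipped with
    a warning; zero variance in both groups yields a flagged, untested
    comparison instead of an infinite statistic.
    """
    if "efficiency" not in df.columns:
        df = add_efficiency(df)
    summary = (
        df.groupby(["reporter_id", "genotype"], sort=False)
        .agg(
            bp_3ss_distance=("bp_3ss_distance", "first"),
            n=("efficiency", "count"),
            mean=("efficiency", "mean"),
            sd=("efficiency", lambda s: s.std(ddof=1)),
        )
        .reset_index()
    )
    rows = []
    for reporter, grp in df.groupby("reporter_id", sort=False):
        genotypes = list(dict.fromkeys(grp["genotype"]))
        if len(genotypes) != 2:
            log.warning("reporter %s: need exactly 2 genotypes, got %d", reporter, len(genotypes))
            continue
        a = grp.loc[grp["genotype"] == genotypes[0], "efficiency"].dropna().to_numpy()
        b = grp.loc[grp["genotype"] == genotypes[1], "efficiency"].dropna().to_numpy()
        if len(a) < 2 or len(b) < 2:
            log.warning("reporter %s: <2 replicates in a group, comparison skipped", reporter)
            continue
        degenerate = np.ptp(a) == 0 and np.ptp(b) == 0
        if degenerate:
            t, p = (0.0 if np.isclose(a.mean(), b.mean()) else math.nan), math.nan
        else:
            t, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append(
            {
                "reporter_id": reporter,
                "bp_3ss_distance": grp["bp_3ss_distance"].iloc[0],
                "group_a": genotypes[0], "group_b": genotypes[1],
                "mean_a": a.mean(), "mean_b": b.mean(),
                "t_stat": t, "p_value": p, "degenerate_variance": degenerate,
            }
        )
    return summary, pd.DataFrame(rows)
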