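"""End-to-end orchestration: filter -> intersect -> merge -> assign ->
canonical -> events -> motifs -> summaries.

``run_pipeline`` consumes a junction manifest (sample_id, genotype, path),
an intron annotation TSV and optionally a genome FASTA, and writes the
event table, distance- and motif-stratified summaries, sequence-logo
PFMs and a machine-readable run log with per-stage record counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
from pyfaidx import Fasta

from . import fans, motifs
from .annotation import assign_junctions_to_genes, call_canonical_sites, read_intron_table
from .errors import ConfigurationError, ParseError
from .junctions import (
    filter_junctions, group_by_genotype, intersect_across_samples,
    merge_replicates, read_sj_table,
)

log = logging.getLogger(__name__)

DEFAULT_DELTA_BINS = (-50, -40, -30, -20, -10, 0, 10, 20, 30, 40, 50)
DEFAULT_BP_BINS = (-20, -10, 0, 10, 20, 30, 40, 50, 60)


@dataclass
class RunConfig:
    manifest: Path
    annotation: Path
    out_dir: Path
    genome: Path | None = None
    wt_genotype: str | None = None  # default: first genotype in the manifest
    mut_genotype: str | None = None
    motif_code_min: int = 1
    unique_reads_min: int = 3
    require_all_samples: bool = True
    pseudocount: float = 0.0
    assignment_window: int = 500
    logo_window: tuple[int, int] = (-9, 2)
    delta_bins: Sequence[float] = DEFAULT_DELTA_BINS
    bp_bins: Sequence[float] = DEFAULT_BP_BINS

    def __post_init__(self):
        if self.motif_code_min < 0 or self.unique_reads_min < 0:
            raise ConfigurationError("filter thresholds must be >= 0")


@dataclass
class PipelineResult:
    events: pd.DataFrame
    summaries: dict[str, pd.DataFrame] = field(default_factory=dict)
    pfms: dict[str, motifs.Pfm] = field(default_factory=dict)
    run_log: dict = field(default_factory=dict)


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    manifest = pd.read_csv(cfg.manifest, sep="\t")
    for col in ("sample_id", "genotype", "path"):
        if col not in manifest.columns:
            raise ParseError(f"manifest missing column {col!r}", path=cfg.manifest)
    base = Path(cfg.manifest).parent
    tables = []
    for row in manifest.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = base / p
        tables.append(read_sj_table(p, row.sample_id, row.genotype))
    counts["parsed"] = sum(len(t) for t in tables)

    tables = [
        filter_junctions(
            t, motif_code_min=cfg.motif_code_min, unique_reads_min=cfg.unique_reads_min
        )
        for t in tables
    ]
    counts["after_false_positive_filter"] = sum(len(t) for t in tables)

    if cfg.require_all_samples:
        tables = intersect_across_samples(tables)
    counts["after_presence_filter"] = sum(len(t) for t in tables)

    groups = group_by_genotype(tables)
    genotype_order = list(groups)
    wt = cfg.wt_genotype or genotype_order[0]
    mut = cfg.mut_genotype or next((g for g in genotype_order if g != wt), wt)
    if wt == mut:
        raise ConfigurationError("need two distinct genotypes for the comparison")
    merged = {g: merge_replicates(ts) for g, ts in groups.items()}
    counts["after_merge"] = sum(len(t) for t in merged.values())

    annotations = read_intron_table(cfg.annotation)
    assignments, drop_counters = assign_junctions_to_genes(
        merged, annotations, window=cfg.assignment_window
    )
    counts["assigned"] = drop_counters["assigned"]
    call_canonical_sites(assignments)

    genome = Fasta(str(cfg.genome)) if cfg.genome is not None else None
    events = fans.build_event_table(
        assignments, wt=wt, mut=mut, genome=genome, pseudocount=cfg.pseudocount
    )
    counts["events"] = len(events)
    fans.write_event_table(events, out_dir / "events.tsv")

    summaries = {
        "by_delta_3ss": fans.summarize_by_bins(events, "delta_3ss", cfg.delta_bins),
        "by_bp_distance": fans.summarize_by_bins(events, "bp_distance", cfg.bp_bins),
        "by_motif_class": motifs.stratify_ratio_by_motif(events)
        if genome is not None
        else pd.DataFrame(),
    }
    for name, df in summaries.items():
        if len(df):
            df.to_csv(out_dir / f"summary_{name}.tsv", sep="\t", index=False, float_format="%.6g")

    pfms: dict[str, motifs.Pfm] = {}
    if genome is not None and len(events):
        pfms = motifs.logos_by_direction(events, genome, window=cfg.logo_window)
        for name, pfm in pfms.items():
            pfm.to_tsv(out_dir / f"pfm_{name}.tsv")

    run_log = {
        "parameters": {
            "motif_code_min": cfg.motif_code_min,
            "unique_reads_min": cfg.unique_reads_min,
            "require_all_samples": cfg.require_all_samples,
            "pseudocount": cfg.pseudocount,
            "assignment_window": cfg.assignment_window,
            "logo_window": list(cfg.logo_window),
            "wt_genotype": wt,
            "mut_genotype": mut,
        },
        "stage_counts": counts,
        "drop_counters": drop_counters,
    }
    with open(out_dir / "run_log.json", "w") as fh:
        json.dump(run_log, fh, indent=2)
    log.info("pipeline finished: %s", counts)
    return PipelineResult(events=events, summaries=summaries, pfms=pfms, run_log=run_log)
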