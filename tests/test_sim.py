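"""Synthetic-data generator: geometry, genome planting, count model, determinism."""

import numpy as np
import pandas as pd
import pytest

from splicefans.errors import ConfigurationError
from splicefans.junctions import read_sj_table
from splicefans.motifs import extract_3ss_sequence
from splicefans.sim import (
    AltSiteSpec, SimulationConfig, build_annotation, build_genome,
    simulate_dataset, simulate_junction_counts, write_genome_fasta,
)


def one_gene_config(strand_fraction, delta=-20, **kw):
    return SimulationConfig(
        n_genes=1, minus_fraction=strand_fraction, seed=5,
        alt_sites=(AltSiteSpec(delta_3ss=delta, wt_usage=0.05, **kw),),
    )


class TestGeometry:
    def test_plus_strand_upstream_acceptor_position(self):
        annotations, truth = build_annotation(one_gene_config(0.0))
        ann = annotations[0]
        assert ann.strand == "+"
        site = truth.sites.iloc[0]
        assert site.acceptor_pos == ann.intron_end - 20
        assert site.delta_3ss == -20 and site.direction == "upstream"

    def test_minus_strand_upstream_acceptor_position(self):
        annotations, truth = build_annotation(one_gene_config(1.0))
        ann = annotations[0]
        assert ann.strand == "-"
        site = truth.sites.iloc[0]
        # transcript-upstream on the minus strand is genomically rightward
        assert site.acceptor_pos == ann.intron_start + 20

    def test_bp_position_consistent_with_offset(self):
        cfg = SimulationConfig(n_genes=10, bp_offset_from_3ss=25, seed=2)
        annotations, truth = build_annotation(cfg)
        for ann in annotations:
            if ann.strand == "+":
                assert ann.acceptor_pos - ann.bp_pos == 25
            else:
                assert ann.bp_pos - ann.acceptor_pos == 25
        # a -20 alt acceptor with BP 25 nt out sits 5 nt downstream of the BP
        assert (truth.sites.bp_distance == 5).all()

    def test_acceptor_outside_gene_rejected(self):
        with pytest.raises(ConfigurationError, match="gene 0"):
            build_annotation(one_gene_config(0.0, delta=-118))

    def test_usage_fractions_sum_to_one_per_genotype(self):
        cfg = SimulationConfig(
            n_genes=4, seed=1,
            alt_sites=(
                AltSiteSpec(-20, 0.05, 5.0),
                AltSiteSpec(-10, 0.02, 2.0, motif_class="NAG_nonY"),
            ),
        )
        _, truth = build_annotation(cfg)
        sites = truth.sites.groupby("gene_id")[["usage_wt", "usage_mut"]].sum()
        merged = truth.genes.set_index("gene_id").join(sites)
        np.testing.assert_allclose(merged.usage_canonical_wt + merged.usage_wt, 1, atol=1e-9)
        np.testing.assert_allclose(merged.usage_canonical_mut + merged.usage_mut, 1, atol=1e-9)

    def test_planted_fans_ratio_equals_fold_change(self):
        _, truth = build_annotation(one_gene_config(0.0, mut_fold_change=5.0))
        site = truth.sites.iloc[0]
        assert site.fans_mut / site.fans_wt == pytest.approx(5.0)
        assert site.log10_fans_ratio == pytest.approx(np.log10(5.0))


class TestGenomePlanting:
    def test_plus_strand_canonical_motif_on_forward_strand(self):
        cfg = one_gene_config(0.0)
        annotations, truth = build_annotation(cfg)
        genome = build_genome(annotations, truth, cfg)
        seq = genome[cfg.chrom_name]
        end = annotations[0].intron_end
        assert seq[end - 3 : end] == "TAG"
        start = annotations[0].intron_start
        assert seq[start - 1 : start + 1] == "GT"

    def test_minus_strand_motif_reverse_complemented(self):
        cfg = one_gene_config(1.0)
        annotations, truth = build_annotation(cfg)
        genome = build_genome(annotations, truth, cfg)
        seq = genome[cfg.chrom_name]
        start = annotations[0].intron_start  # canonical acceptor on minus strand
        assert seq[start - 1 : start + 2] == "CTA"

    @pytest.mark.parametrize("minus", [0.0, 1.0])
    @pytest.mark.parametrize(
        "motif_class,motif",
        [("YAG", "CAG"), ("NAG_nonY", "GAG"), ("HAU", "AAU"), ("BG", "UGG"), ("OTHER", "GAC")],
    )
    def test_planted_motif_round_trips_through_extraction(self, minus, motif_class, motif):
        cfg = one_gene_config(minus, motif_class=motif_class)
        annotations, truth = build_annotation(cfg)
        genome = build_genome(annotations, truth, cfg)
        site = truth.sites.iloc[0]
        got = extract_3ss_sequence(
            genome, cfg.chrom_name, int(site.acceptor_pos), site.strand, window=(-2, 0)
        )
        assert got == motif

    def test_conflicting_overlapping_motifs_rejected(self):
        cfg = SimulationConfig(
            n_genes=1, minus_fraction=0.0, seed=5,
            alt_sites=(
                AltSiteSpec(-20, 0.02, motif_class="NAG_nonY"),
                AltSiteSpec(-21, 0.02, motif_class="NAG_nonY"),  # overlaps with different letters
            ),
        )
        annotations, truth = build_annotation(cfg)
        with pytest.raises(ConfigurationError, match="conflicting"):
            build_genome(annotations, truth, cfg)

    def test_fasta_round_trip(self, tmp_path):
        from pyfaidx import Fasta

        cfg = one_gene_config(0.0)
        annotations, truth = build_annotation(cfg)
        genome = build_genome(annotations, truth, cfg)
        path = tmp_path / "g.fa"
        write_genome_fasta(genome, path)
        fa = Fasta(str(path))
        assert str(fa[cfg.chrom_name][:]) == genome[cfg.chrom_name]


class TestCounts:
    def test_zero_usage_site_has_zero_counts(self):
        cfg = one_gene_config(0.0)
        cfg = SimulationConfig(
            n_genes=1, minus_fraction=0.0, seed=5,
            alt_sites=(AltSiteSpec(-20, 0.0),),
        )
        annotations, truth = build_annotation(cfg)
        tables = simulate_junction_counts(annotations, truth, cfg)
        for table in tables.values():
            alt = [r for r in table if not r.annotated_flag]
            assert all(r.unique_reads == 0 for r in alt)

    def test_poisson_mean_matches_planted_usage(self):
        # canonical usage 0.8 at depth 1000 over 100 replicates
        cfg = SimulationConfig(
            n_genes=1, minus_fraction=0.0, expression_mean=1000.0,
            replicates_per_genotype=100, seed=9,
            alt_sites=(AltSiteSpec(-20, 0.2),),
        )
        annotations, truth = build_annotation(cfg)
        tables = simulate_junction_counts(annotations, truth, cfg)
        counts = [
            next(r.unique_reads for r in t if r.annotated_flag)
            for (g, _), t in tables.items()
            if g == cfg.genotypes[0]
        ]
        mean = np.mean(counts)
        se = np.sqrt(800 / len(counts))
        assert abs(mean - 800) < 3 * se

    def test_negative_binomial_is_overdispersed(self):
        cfg = SimulationConfig(
            n_genes=1, minus_fraction=0.0, expression_mean=500.0,
            replicates_per_genotype=200, noise_model="negative_binomial",
            nb_dispersion=0.2, seed=9, alt_sites=(),
        )
        annotations, truth = build_annotation(cfg)
        tables = simulate_junction_counts(annotations, truth, cfg)
        counts = [
            next(iter(t)).unique_reads
            for (g, _), t in tables.items()
            if g == cfg.genotypes[0]
        ]
        assert np.var(counts) > np.mean(counts)

    def test_unknown_noise_model_rejected(self):
        with pytest.raises(ConfigurationError, match="noise_model"):
            SimulationConfig(n_genes=1, noise_model="gaussian").validate()

    def test_adding_replicates_preserves_existing_streams(self):
        base = SimulationConfig(n_genes=3, replicates_per_genotype=2, seed=4)
        more = SimulationConfig(n_genes=3, replicates_per_genotype=3, seed=4)
        ann_b, truth_b = build_annotation(base)
        ann_m, truth_m = build_annotation(more)
        t_base = simulate_junction_counts(ann_b, truth_b, base)
        t_more = simulate_junction_counts(ann_m, truth_m, more)
        for key, table in t_base.items():
            assert [r.unique_reads for r in table] == [r.unique_reads for r in t_more[key]]


class TestDeterminism:
    def test_identical_config_yields_byte_identical_outputs(self, tmp_path):
        cfg = SimulationConfig(n_genes=5, seed=42)
        p1 = simulate_dataset(cfg, tmp_path / "a")
        p2 = simulate_dataset(cfg, tmp_path / "b")
        for name in ("annotation", "genome", "truth_sites", "manifest"):
            assert p1[name].read_bytes() == p2[name].read_bytes()
        for f in sorted((tmp_path / "a").glob("*.SJ.out.tab")):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()

    def test_sj_round_trip_through_reader(self, tmp_path):
        cfg = SimulationConfig(n_genes=5, seed=42)
        paths = simulate_dataset(cfg, tmp_path)
        manifest = pd.read_csv(paths["manifest"], sep="\t")
        annotations, truth = build_annotation(cfg)
        tables = simulate_junction_counts(annotations, truth, cfg)
        for row in manifest.itertuples(index=False):
            back = read_sj_table(tmp_path / row.path, row.sample_id, row.genotype)
            genotype = row.genotype
            rep = int(row.sample_id.rsplit("rep", 1)[1])
            orig = tables[(genotype, rep)]
            assert [r.key for r in back] == [r.key for r in orig]
            assert [r.unique_reads for r in back] == [r.unique_reads for r in orig]
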