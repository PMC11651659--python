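"""Junction table parsing, filtering, intersection and replicate merging."""

import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from splicefans.errors import ConsistencyError, ParseError
from splicefans.junctions import (
    JunctionRecord, JunctionTable, filter_junctions, intersect_across_samples,
    merge_replicates, read_sj_table, write_sj_table,
)


def make_record(start=100, end=195, strand="+", motif=1, unique=57, chrom="chrI", **kw):
    return JunctionRecord(
        chrom=chrom, intron_start=start, intron_end=end, strand=strand,
        motif_code=motif, annotated_flag=kw.get("annotated", 0),
        unique_reads=unique, multi_reads=kw.get("multi", 0),
        max_overhang=kw.get("overhang", 38),
    )


def make_table(records, sample_id="s1", genotype="wt"):
    t = JunctionTable(sample_id=sample_id, genotype=genotype)
    for r in records:
        t.add(r)
    return t


class TestParsing:
    def test_well_formed_line(self, tmp_path):
        p = tmp_path / "a.SJ.out.tab"
        p.write_text("chrI\t100\t195\t1\t1\t0\t57\t3\t38\n")
        table = read_sj_table(p, "s1", "wt")
        (rec,) = list(table)
        assert rec.chrom == "chrI"
        assert (rec.intron_start, rec.intron_end) == (100, 195)
        assert rec.strand == "+"
        assert (rec.motif_code, rec.annotated_flag) == (1, 0)
        assert (rec.unique_reads, rec.multi_reads, rec.max_overhang) == (57, 3, 38)

    def test_strand_codes_map_to_symbols(self, tmp_path):
        p = tmp_path / "a.tab"
        p.write_text(
            "chrI\t100\t195\t1\t1\t0\t5\t0\t38\n"
            "chrI\t300\t420\t2\t1\t0\t5\t0\t38\n"
            "chrI\t600\t700\t0\t1\t0\t5\t0\t38\n"
        )
        strands = [r.strand for r in read_sj_table(p, "s1", "wt")]
        assert strands == ["+", "-", "."]

    @pytest.mark.parametrize(
        "line",
        [
            "chrI\t100\t195\t1\t1\t0\t57\t3",  # 8 columns
            "chrI\t100\tabc\t1\t1\t0\t57\t3\t38",  # non-integer
            "chrI\t0\t195\t1\t1\t0\t57\t3\t38",  # coordinate < 1
            "chrI\t100\t195\t5\t1\t0\t57\t3\t38",  # bad strand code
        ],
    )
    def test_malformed_line_raises_with_line_number(self, tmp_path, line):
        p = tmp_path / "bad.tab"
        p.write_text("chrI\t1\t10\t1\t1\t0\t5\t0\t20\n" + line + "\n")
        with pytest.raises(ParseError, match=r":2"):
            read_sj_table(p, "s1", "wt")

    def test_duplicate_key_rejected(self, tmp_path):
        p = tmp_path / "dup.tab"
        p.write_text("chrI\t100\t195\t1\t1\t0\t5\t0\t38\n" * 2)
        with pytest.raises(ParseError, match="duplicate"):
            read_sj_table(p, "s1", "wt")

    def test_empty_file_gives_empty_table(self, tmp_path):
        p = tmp_path / "empty.tab"
        p.write_text("")
        assert len(read_sj_table(p, "s1", "wt")) == 0

    def test_round_trip_preserves_all_fields(self, tmp_path):
        records = [
            make_record(start=10 * i + 1, end=10 * i + 5, strand=s, motif=m,
                        unique=u, multi=i, overhang=20 + i)
            for i, (s, m, u) in enumerate(
                [("+", 1, 0), ("-", 2, 7), (".", 0, 3)] * 17  # arbitrary mix, 51 records
            )
        ]
        table = make_table(records)
        p = tmp_path / "rt.tab"
        write_sj_table(table, p)
        back = read_sj_table(p, "s1", "wt")
        for orig, new in zip(table, back):
            assert dataclasses.replace(new, line_no=None) == orig


class TestFilter:
    @pytest.mark.parametrize(
        "motif,unique,kept",
        [
            (0, 100, False),  # non-canonical motif removed regardless of depth
            (1, 2, False),  # too few unique reads
            (1, 3, True),  # minimum passing depth
            (1, 0, False),  # multi-mapper-only support
        ],
    )
    def test_keep_rules(self, motif, unique, kept):
        table = make_table([make_record(motif=motif, unique=unique)])
        assert (len(filter_junctions(table)) == 1) is kept

    def test_filter_is_idempotent_and_monotone(self):
        records = [
            make_record(start=i * 10 + 1, end=i * 10 + 5, motif=i % 3, unique=i)
            for i in range(12)
        ]
        table = make_table(records)
        once = filter_junctions(table)
        twice = filter_junctions(once)
        assert list(once.records) == list(twice.records)
        assert len(once) <= len(table)
        assert all(r.motif_code > 0 and r.unique_reads > 2 for r in once)

    @given(
        st.lists(
            st.tuples(st.integers(0, 6), st.integers(0, 50)),
            min_size=0, max_size=30, unique=True,
        )
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_filter_agrees_with_predicate(self, specs):
        records = [
            make_record(start=100 + 10 * i, end=105 + 10 * i, motif=m, unique=u)
            for i, (m, u) in enumerate(specs)
        ]
        table = make_table(records)
        expected = {r.key for r in records if r.motif_code > 0 and r.unique_reads > 2}
        assert set(filter_junctions(table).records) == expected

    def test_input_table_unmodified(self):
        table = make_table([make_record(motif=0)])
        filter_junctions(table)
        assert len(table) == 1


class TestIntersect:
    def test_junction_in_three_of_four_samples_dropped(self):
        shared = make_record()
        extra = make_record(start=500, end=600)
        tables = [
            make_table([shared, extra], sample_id=f"s{i}") for i in range(3)
        ] + [make_table([shared], sample_id="s3")]
        out = intersect_across_samples(tables)
        for t in out:
            assert set(t.records) == {shared.key}

    def test_single_table_unchanged(self):
        t = make_table([make_record()])
        (out,) = intersect_across_samples([t])
        assert set(out.records) == set(t.records)

    def test_disjoint_tables_all_empty(self):
        t1 = make_table([make_record(start=1, end=5)])
        t2 = make_table([make_record(start=11, end=15)], sample_id="s2")
        assert all(len(t) == 0 for t in intersect_across_samples([t1, t2]))


class TestMerge:
    def test_counts_summed_across_replicates(self):
        t1 = make_table([make_record(unique=40, multi=1)], sample_id="r1")
        t2 = make_table([make_record(unique=60, multi=2)], sample_id="r2")
        merged = merge_replicates([t1, t2])
        (rec,) = list(merged)
        assert (rec.unique_reads, rec.multi_reads) == (100, 3)

    def test_three_replicates_sum(self):
        tables = [
            make_table([make_record(unique=u)], sample_id=f"r{u}")
            for u in (10, 20, 30)
        ]
        assert next(iter(merge_replicates(tables))).unique_reads == 60

    def test_single_replicate_identity(self):
        t = make_table([make_record(unique=5)])
        assert next(iter(merge_replicates([t]))).unique_reads == 5

    def test_conflicting_motif_rejected(self):
        t1 = make_table([make_record(motif=1)], sample_id="r1")
        t2 = make_table([make_record(motif=2)], sample_id="r2")
        with pytest.raises(ConsistencyError):
            merge_replicates([t1, t2])

    def test_mixed_genotypes_rejected(self):
        t1 = make_table([make_record()], genotype="wt")
        t2 = make_table([make_record()], genotype="mut")
        with pytest.raises(ConsistencyError):
            merge_replicates([t1, t2])

    def test_merge_linearity_under_replication(self):
        base = [make_record(unique=7, multi=2), make_record(start=500, end=600, unique=3)]
        for k in (1, 2, 5):
            tables = [make_table(base, sample_id=f"r{i}") for i in range(k)]
            merged = merge_replicates(tables)
            assert [r.unique_reads for r in merged] == [7 * k, 3 * k]
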