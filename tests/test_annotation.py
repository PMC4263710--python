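"""Annotation module: GTF I/O, merging, classification, gaps, neighbors."""

import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_gene, random_geneset
from ontomap.annotation import (
    GeneModel,
    GeneSet,
    GtfParseError,
    classify_genes,
    gene_gap,
    merge_nonoverlapping,
    nearest_coding_neighbor,
    read_gtf,
    write_gtf,
)


class TestReadGtf:
    def test_coordinate_conversion(self, tmp_path):
        # 1-based inclusive 101..200 -> 0-based half-open (100, 200)
        p = tmp_path / "a.gtf"
        p.write_text('chr1\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "g1";\n')
        gs = read_gtf(p)
        assert gs["g1"].span == (100, 200)

    def test_multi_exon_span_is_min_max(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text(
            'chr1\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "g1";\n'
            'chr1\tsrc\texon\t301\t400\t.\t+\t.\tgene_id "g1";\n'
        )
        g = read_gtf(p)["g1"]
        assert g.span == (100, 400)
        assert g.exons == ((100, 200), (300, 400))

    def test_biotype_from_attributes(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text(
            'chr1\tsrc\texon\t1\t50\t.\t+\t.\tgene_id "g1"; gene_biotype "antisense";\n'
            'chr1\tsrc\texon\t100\t150\t.\t+\t.\tgene_id "g2";\n'
        )
        gs = read_gtf(p)
        assert gs["g1"].biotype == "antisense"
        assert gs["g2"].biotype == "unknown"

    @pytest.mark.parametrize(
        "line,msg",
        [
            ("chr1\tsrc\texon\t101\t200\t.\t+\t.", "9 tab-separated fields"),
            ('chr1\tsrc\texon\tx\t200\t.\t+\t.\tgene_id "g";', "non-integer"),
            ('chr1\tsrc\texon\t101\t200\t.\t+\t.\tfoo "bar";', "gene_id"),
            ('chr1\tsrc\texon\t201\t200\t.\t+\t.\tgene_id "g";', "invalid coordinate"),
        ],
    )
    def test_malformed_lines_name_line_number(self, tmp_path, line, msg):
        p = tmp_path / "bad.gtf"
        p.write_text("# header\n" + line + "\n")
        with pytest.raises(GtfParseError, match=msg) as exc:
            read_gtf(p)
        assert "line 2" in str(exc.value)

    def test_round_trip_identity(self, tmp_path, rng):
        genes = []
        for i in range(5):
            start = int(rng.integers(0, 100_000))
            mid = start + int(rng.integers(100, 1_000))
            end = mid + int(rng.integers(200, 1_000))
            genes.append(
                GeneModel(
                    gene_id=f"g{i}", chrom=f"chr{i % 2 + 1}",
                    strand="+" if i % 2 else "-", start=start, end=end,
                    exons=((start, mid), (mid + 50, end)),
                    biotype=["protein_coding", "lincRNA", "unknown", "snoRNA", "antisense"][i],
                    source="roundtrip",
                )
            )
        gs = GeneSet(genes)
        path = tmp_path / "rt.gtf"
        write_gtf(gs, path)
        assert read_gtf(path) == gs


class TestMerge:
    def test_overlapping_secondary_excluded(self):
        primary = GeneSet([make_gene("p1", start=150, end=250)])
        secondary = GeneSet([make_gene("s1", start=100, end=200)])
        merged = merge_nonoverlapping(primary, secondary)
        assert "s1" not in merged

    def test_abutting_secondary_kept(self):
        # half-open spans: (100,200) and (200,300) do not overlap
        primary = GeneSet([make_gene("p1", start=200, end=300)])
        secondary = GeneSet([make_gene("s1", start=100, end=200)])
        merged = merge_nonoverlapping(primary, secondary)
        assert "s1" in merged
        assert merged["s1"].source == "secondary"
        assert merged["p1"].source == "primary"

    def test_overlap_is_strand_agnostic(self):
        primary = GeneSet([make_gene("p1", start=100, end=200, strand="+")])
        secondary = GeneSet([make_gene("s1", start=150, end=250, strand="-")])
        assert "s1" not in merge_nonoverlapping(primary, secondary)

    def test_matches_brute_force_scan(self, rng):
        primary = random_geneset(rng, 20, max_pos=50_000)
        sec = random_geneset(rng, 20, max_pos=50_000)
        secondary = GeneSet(
            [make_gene(f"S{g.gene_id}", chrom=g.chrom, strand=g.strand,
                       start=g.start, end=g.end) for g in sec]
        )
        merged = merge_nonoverlapping(primary, secondary)
        for s in secondary:
            overlaps = any(
                p.chrom == s.chrom and s.start < p.end and p.start < s.end
                for p in primary
            )
            assert (s.gene_id in merged) == (not overlaps)

    def test_idempotent(self, rng):
        primary = random_geneset(rng, 15, max_pos=40_000)
        sec = random_geneset(rng, 15, max_pos=40_000)
        secondary = GeneSet(
            [make_gene(f"S{g.gene_id}", chrom=g.chrom, start=g.start, end=g.end)
             for g in sec]
        )
        once = merge_nonoverlapping(primary, secondary)
        twice = merge_nonoverlapping(once, secondary)
        assert len(twice) == len(once)


class TestClassify:
    @pytest.mark.parametrize(
        "biotype,klass",
        [
            ("protein_coding", "coding"),
            ("snoRNA", "small_rna"),
            ("miRNA", "small_rna"),
            ("misc_RNA", "small_rna"),
            ("antisense", "lncRNA"),
            ("lincRNA", "lncRNA"),
            ("processed_transcript", "lncRNA"),
            ("unknown", "lncRNA"),  # secondary models without biotype
        ],
    )
    def test_biotype_mapping(self, biotype, klass):
        gs = classify_genes(GeneSet([make_gene("g", biotype=biotype)]))
        assert gs["g"].klass == klass


class TestGeneGap:
    def test_abutting_is_zero(self):
        a = make_gene("a", start=100, end=200)
        b = make_gene("b", start=200, end=300)
        assert gene_gap(a, b) == 0

    def test_separated(self):
        a = make_gene("a", start=100, end=200)
        b = make_gene("b", start=250, end=300)
        assert gene_gap(a, b) == 50

    def test_overlap_is_zero(self):
        a = make_gene("a", start=100, end=200)
        b = make_gene("b", start=150, end=250)
        assert gene_gap(a, b) == 0

    def test_different_chromosomes_undefined(self):
        a = make_gene("a", chrom="chr1")
        b = make_gene("b", chrom="chr2")
        assert gene_gap(a, b) is None

    @given(
        s1=st.integers(0, 10_000), l1=st.integers(1, 5_000),
        s2=st.integers(0, 10_000), l2=st.integers(1, 5_000),
    )
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_symmetric_and_self_zero(self, s1, l1, s2, l2):
        a = make_gene("a", start=s1, end=s1 + l1)
        b = make_gene("b", start=s2, end=s2 + l2)
        assert gene_gap(a, b) == gene_gap(b, a)
        assert gene_gap(a, a) == 0


class TestNearestNeighbor:
    def test_minimizes_gap(self):
        g = make_gene("x", start=500, end=600, biotype="lincRNA", klass="lncRNA")
        gs = GeneSet([
            g,
            make_gene("c1", start=100, end=200, klass="coding"),
            make_gene("c2", start=700, end=800, klass="coding"),
        ])
        p = nearest_coding_neighbor(g, gs)
        assert (p.id_b, p.gap_bp, p.pair_class) == ("c2", 100, "PC-NC")

    def test_tie_broken_by_start(self):
        g = make_gene("x", start=500, end=600, klass="coding")
        gs = GeneSet([
            g,
            make_gene("left", start=300, end=400, klass="coding"),
            make_gene("right", start=700, end=800, klass="coding"),
        ])
        p = nearest_coding_neighbor(g, gs)
        assert p.id_b == "left"
        assert p.pair_class == "PC-PC"

    def test_no_coding_gene_on_chromosome(self):
        g = make_gene("x", chrom="chrX", klass="lncRNA", biotype="lincRNA")
        gs = GeneSet([g, make_gene("c", chrom="chr1", klass="coding")])
        assert nearest_coding_neighbor(g, gs) is None

    def test_excludes_self(self):
        g = make_gene("x", start=100, end=200, klass="coding")
        other = make_gene("y", start=500, end=600, klass="coding")
        p = nearest_coding_neighbor(g, GeneSet([g, other]))
        assert p.id_b == "y"

    def test_matches_brute_force(self, rng):
        gs = random_geneset(rng, 50)
        for g in gs:
            expected = None
            for cand in gs:
                if cand.gene_id == g.gene_id or cand.klass != "coding":
                    continue
                gap = gene_gap(g, cand)
                if gap is None:
                    continue
                key = (gap, cand.start, cand.gene_id)
                if expected is None or key < expected:
                    expected = key
            got = nearest_coding_neighbor(g, gs)
            if expected is None:
                assert got is None
            else:
                assert (got.gap_bp, gs[got.id_b].start, got.id_b) == expected
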