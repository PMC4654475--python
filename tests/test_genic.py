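"""Gene-centric piC calling: region counting, UTR extension, curation."""
import pytest

from picluster import (
    GenomicInterval, GeneModel, Thresholds, apply_curation_filters,
    call_genic_pics, count_gene_regions, extend_utr,
)
from picluster.genic import same_strand_neighbor_bound
from tests.conftest import make_track

LIB = 1_000_000  # 1 read == 1 RPM


def simple_gene(name="g1", start=1000, strand="+", utr3_len=800):
    # single exon: utr5 100, orf 600, utr3 utr3_len
    end = start + 700 + utr3_len
    if strand == "+":
        cds = (start + 100, start + 700)
    else:
        cds = (start + utr3_len, end - 100)
    return GeneModel(
        name, name, "chr1", start, end, strand,
        [GenomicInterval("chr1", start, end, strand)], cds[0], cds[1],
    )


class TestCountRegions:
    def test_counts_only_mrna_strand(self):
        g = simple_gene()  # utr3 = [1700, 2500) on +
        plus = make_track({"chr1": {1800: 100}}, "+", LIB)
        minus = make_track({"chr1": {1800: 500}}, "-", LIB)
        gc = count_gene_regions(g, plus, minus, extend=False)
        assert gc.utr3_count == 100

    def test_two_exon_utr3_sums_blocks_excludes_intron(self):
        # exons [0,1000) and [2000,3000); CDS [100,500): 3'UTR = [500,1000)+[2000,3000)
        g = GeneModel(
            "g", "g", "chr1", 0, 3000, "+",
            [GenomicInterval("chr1", 0, 1000, "+"),
             GenomicInterval("chr1", 2000, 3000, "+")],
            100, 500,
        )
        plus = make_track(
            {"chr1": {600: 5, 1500: 99, 2500: 7}}, "+", LIB
        )  # 1500 is intronic
        minus = make_track({"chr1": {}}, "-", LIB)
        gc = count_gene_regions(g, plus, minus, extend=False)
        assert gc.utr3_count == 12
        assert gc.orf_count == 0

    def test_rpm_threshold_boundary(self):
        g = simple_gene()
        plus = make_track({"chr1": {1800: 10}}, "+", LIB)
        minus = make_track({"chr1": {}}, "-", LIB)
        gc = count_gene_regions(g, plus, minus, extend=False)
        assert gc.utr3_rpm == pytest.approx(10.0)


class TestExtendUtr:
    def test_no_reads_no_extension(self):
        g = simple_gene()  # ends at 2500
        track = make_track({"chr1": {}}, "+", LIB)
        assert extend_utr(g, track, 2000) is None

    def test_mammal_one_window_captures_reads_at_1500(self):
        g = simple_gene()  # + strand, gene end 2500
        track = make_track({"chr1": {2500 + 1500: 2}}, "+", LIB)
        ext = extend_utr(g, track, 2000, min_rpm=1.0)
        assert (ext.start, ext.end) == (2500, 4500)

    def test_fly_windows_stop_before_far_reads(self):
        # same track, 500 bp windows: windows 1-3 are silent, never reach +1500
        g = simple_gene()
        track = make_track({"chr1": {2500 + 1500: 2}}, "+", LIB)
        assert extend_utr(g, track, 500, min_rpm=1.0) is None

    def test_fly_iterates_while_each_window_passes(self):
        g = simple_gene()
        track = make_track(
            {"chr1": {2600: 1, 3100: 1, 3600: 1}}, "+", LIB
        )  # one read in each of windows 1..3
        ext = extend_utr(g, track, 500, min_rpm=1.0)
        assert (ext.start, ext.end) == (2500, 4000)

    def test_extension_capped_at_max_windows(self):
        g = simple_gene()
        data = {2500 + 2000 * i + 10: 5 for i in range(10)}
        track = make_track({"chr1": data}, "+", LIB)
        ext = extend_utr(g, track, 2000, min_rpm=1.0, max_windows=5)
        assert len(ext) == 5 * 2000

    def test_extension_clipped_at_neighbor(self):
        g = simple_gene()
        track = make_track({"chr1": {2600: 5}}, "+", LIB)
        ext = extend_utr(g, track, 2000, min_rpm=1.0, neighbor_bound=3000)
        assert (ext.start, ext.end) == (2500, 3000)

    def test_extension_clipped_at_chromosome_end(self):
        g = simple_gene()
        track = make_track({"chr1": {2600: 5}}, "+", LIB)
        ext = extend_utr(g, track, 2000, min_rpm=1.0, chrom_size=2800)
        assert (ext.start, ext.end) == (2500, 2800)

    def test_minus_strand_extends_leftwards(self):
        g = simple_gene(strand="-")  # utr3 at [1000,1800); transcript 3' end = 1000
        track = make_track({"chr1": {500: 3}}, "-", LIB)
        ext = extend_utr(g, track, 2000, min_rpm=1.0)
        assert (ext.start, ext.end) == (0, 1000)

    def test_neighbor_bound_finds_nearest_same_strand_gene(self):
        g1 = simple_gene("a", start=1000, strand="+")
        g2 = simple_gene("b", start=10_000, strand="-")
        g3 = simple_gene("c", start=20_000, strand="+")
        assert same_strand_neighbor_bound(g1, [g1, g2, g3]) == 20_000


class TestCallGenic:
    def test_retention_boundary_is_inclusive(self):
        ga = simple_gene("a", start=1000)
        gb = simple_gene("b", start=10_000)
        # lib 1e8: 999 reads = 9.99 RPM (excluded), 1000 reads = 10.0 (included)
        plus = make_track({"chr1": {1800: 999, 10_800: 1000}}, "+", 100_000_000)
        minus = make_track({"chr1": {}}, "-", 100_000_000)
        called = call_genic_pics([ga, gb], plus, minus, extend=False)
        assert [c.name for c in called] == ["b"]

    def test_orf_retained_flag(self):
        g = simple_gene("a", start=1000)  # orf [1100,1700)
        plus = make_track({"chr1": {1200: 60, 1800: 15}}, "+", LIB)
        minus = make_track({"chr1": {}}, "-", LIB)
        (c,) = call_genic_pics([g], plus, minus, extend=False)
        assert c.orf_retained

    def test_raising_threshold_never_adds_loci(self):
        genes = [simple_gene(f"g{i}", start=1000 + 10_000 * i) for i in range(10)]
        data = {1800 + 10_000 * i: 5 * i for i in range(10)}
        plus = make_track({"chr1": data}, "+", LIB)
        minus = make_track({"chr1": {}}, "-", LIB)
        loose = {c.name for c in call_genic_pics(
            genes, plus, minus, Thresholds(genic_min_rpm=10), extend=False)}
        strict = {c.name for c in call_genic_pics(
            genes, plus, minus, Thresholds(genic_min_rpm=20), extend=False)}
        assert strict <= loose
        assert len(strict) < len(loose)

    def test_output_order_deterministic(self):
        genes = [simple_gene(f"g{i}", start=1000 + 10_000 * i) for i in range(5)]
        data = {1800 + 10_000 * i: 50 for i in range(5)}
        plus = make_track({"chr1": data}, "+", LIB)
        minus = make_track({"chr1": {}}, "-", LIB)
        a = call_genic_pics(genes, plus, minus, extend=False)
        b = call_genic_pics(list(reversed(genes)), plus, minus, extend=False)
        assert [c.name for c in a] == [c.name for c in b]


class TestCuration:
    def _candidates(self, names, track_data=None):
        genes = [simple_gene(n, start=1000 + 10_000 * i)
                 for i, n in enumerate(names)]
        data = track_data or {1800 + 10_000 * i: 50 for i in range(len(names))}
        plus = make_track({"chr1": data}, "+", LIB)
        minus = make_track({"chr1": {}}, "-", LIB)
        return call_genic_pics(genes, plus, minus, extend=False), plus, minus

    def test_te_dominated_utr3_removed(self):
        cands, plus, minus = self._candidates(["a"])
        # repeat annotation covering the whole 3'UTR
        te = [GenomicInterval("chr1", 1700, 2500)]
        res = apply_curation_filters(cands, plus, minus, te_annotation=te)
        assert res.kept == []
        assert res.removed[0].reason == "TE_overlap"

    def test_te_outside_utr3_kept(self):
        cands, plus, minus = self._candidates(["a"])
        te = [GenomicInterval("chr1", 5000, 6000)]
        res = apply_curation_filters(cands, plus, minus, te_annotation=te)
        assert len(res.kept) == 1

    def test_duplicate_names_keep_one(self):
        cands, plus, minus = self._candidates(["dup", "dup"])
        res = apply_curation_filters(cands, plus, minus)
        assert len(res.kept) == 1
        assert res.removed[0].reason == "duplicate_name"

    def test_gm_identifier_removed(self):
        cands, plus, minus = self._candidates(["Gm12345"])
        res = apply_curation_filters(cands, plus, minus)
        assert res.removed[0].reason == "ncRNA_pattern"

    def test_blacklist_family_removed(self):
        cands, plus, minus = self._candidates(["Olfr1234"])
        res = apply_curation_filters(cands, plus, minus)
        assert res.removed[0].reason == "blacklist_family"
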