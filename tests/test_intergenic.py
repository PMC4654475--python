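"""Sliding-window intergenic cluster calling and synteny anchoring."""
import numpy as np
import pytest

from picluster import GenomicInterval, call_intergenic_pics
from picluster.intergenic import anchor_by_synteny, IntergenicPiC
from picluster.io import OrthologMap
from tests.conftest import make_track
from tests.test_genic import simple_gene

LIB = 1_000_000
W = 5000


def spread(window_idx, rpm, per=10):
    """Place `rpm` reads (lib 1e6) spread over window `window_idx`."""
    base = window_idx * W
    n = int(rpm)
    return {base + 13 * i: n // per for i in range(per)} if n % per == 0 else {
        base + 13 * i: 1 for i in range(n)
    }


def oracle_scan(plus_map, minus_map, size, window=W, start_rpm=1.0,
                stop_rpm=1.0, min_total=10.0, lib=LIB):
    """Independent per-base linear scan used as the calling oracle."""
    cov = np.zeros(size)
    for strand_map in (plus_map, minus_map):
        for p, v in strand_map.get("chr1", {}).items():
            if p < size:
                cov[p] += v
    clusters = []
    run = None  # [start, end, total_reads]
    pos = 0
    while pos < size:
        end = min(pos + window, size)
        reads = cov[pos:end].sum()
        rpm = reads * 1e6 / lib
        if run is None:
            if rpm > start_rpm:
                run = [pos, end, reads]
        else:
            if rpm >= stop_rpm:
                run[1] = end
                run[2] += reads
            else:
                if run[2] * 1e6 / lib >= min_total:
                    clusters.append(tuple(run[:2]))
                run = None
                if rpm > start_rpm:
                    run = [pos, end, reads]
        pos = end
    if run is not None and run[2] * 1e6 / lib >= min_total:
        clusters.append(tuple(run[:2]))
    return clusters


class TestCalling:
    def test_flat_track_yields_nothing(self):
        plus = make_track({"chr1": {}}, "+", LIB)
        minus = make_track({"chr1": {}}, "-", LIB)
        assert call_intergenic_pics(plus, minus,
                                    chrom_sizes={"chr1": 50_000}) == []

    def test_total_threshold_drops_weak_cluster(self):
        # windows at 2/3/2 RPM -> one run, total 7 < 10: dropped
        data = {}
        for w, rpm in ((2, 2), (3, 3), (4, 2)):
            data.update({w * W + 11 * i: 1 for i in range(rpm)})
        plus = make_track({"chr1": data}, "+", LIB)
        minus = make_track({"chr1": {}}, "-", LIB)
        assert call_intergenic_pics(plus, minus,
                                    chrom_sizes={"chr1": 60_000}) == []

    def test_qualifying_cluster_merges_contiguous_windows(self):
        data = {}
        for w in (2, 3, 4):
            data.update({w * W + 11 * i: 1 for i in range(4)})  # 4 RPM each
        plus = make_track({"chr1": data}, "+", LIB)
        minus = make_track({"chr1": {}}, "-", LIB)
        (cl,) = call_intergenic_pics(plus, minus, chrom_sizes={"chr1": 60_000})
        assert (cl.interval.start, cl.interval.end) == (2 * W, 5 * W)
        assert cl.total_rpm == pytest.approx(12.0)
        assert cl.window_trace == pytest.approx([4.0, 4.0, 4.0])

    def test_both_strands_combine_for_detection(self):
        plus = make_track({"chr1": {W * 2 + i: 1 for i in range(6)}}, "+", LIB)
        minus = make_track({"chr1": {W * 2 + 100 + i: 1 for i in range(6)}}, "-", LIB)
        (cl,) = call_intergenic_pics(plus, minus, chrom_sizes={"chr1": 30_000})
        assert cl.plus_rpm == pytest.approx(6.0)
        assert cl.minus_rpm == pytest.approx(6.0)

    def test_window_larger_than_chromosome(self):
        plus = make_track({"chr1": {i: 4 for i in range(5)}}, "+", LIB)
        minus = make_track({"chr1": {}}, "-", LIB)
        (cl,) = call_intergenic_pics(plus, minus, chrom_sizes={"chr1": 1000})
        assert (cl.interval.start, cl.interval.end) == (0, 1000)

    def test_equals_bruteforce_oracle_on_random_tracks(self, rng):
        size = 200_000
        for _ in range(30):
            n = int(rng.integers(0, 400))
            plus_map = {"chr1": {}}
            minus_map = {"chr1": {}}
            for p in rng.integers(0, size, n):
                plus_map["chr1"][int(p)] = plus_map["chr1"].get(int(p), 0) + 1
            for p in rng.integers(0, size, int(rng.integers(0, 400))):
                minus_map["chr1"][int(p)] = minus_map["chr1"].get(int(p), 0) + 1
            plus = make_track(plus_map, "+", 100_000)
            minus = make_track(minus_map, "-", 100_000)
            got = [
                (c.interval.start, c.interval.end)
                for c in call_intergenic_pics(
                    plus, minus, chrom_sizes={"chr1": size}
                )
            ]
            want = oracle_scan(plus_map, minus_map, size, lib=100_000)
            assert got == want

    def test_translation_invariance(self):
        data = {2 * W + 11 * i: 1 for i in range(15)}
        shift = 7 * W
        plus_a = make_track({"chr1": data}, "+", LIB)
        plus_b = make_track(
            {"chr1": {p + shift: v for p, v in data.items()}}, "+", LIB
        )
        empty = make_track({"chr1": {}}, "-", LIB)
        (a,) = call_intergenic_pics(plus_a, empty, chrom_sizes={"chr1": 100_000})
        (b,) = call_intergenic_pics(plus_b, empty, chrom_sizes={"chr1": 100_000})
        assert b.interval.start - a.interval.start == shift
        assert b.total_rpm == a.total_rpm

    def test_window_trace_replays_start_stop_rule(self):
        data = {}
        for w in (1, 2, 5, 6, 7):
            data.update({w * W + 9 * i: 1 for i in range(8)})
        plus = make_track({"chr1": data}, "+", LIB)
        minus = make_track({"chr1": {}}, "-", LIB)
        clusters = call_intergenic_pics(plus, minus, chrom_sizes={"chr1": 60_000})
        assert len(clusters) == 2
        for cl in clusters:
            assert cl.window_trace[0] > 1.0
            assert all(w >= 1.0 for w in cl.window_trace)

    def test_genic_overlap_drop_mode(self):
        data = {2 * W + 11 * i: 1 for i in range(15)}
        plus = make_track({"chr1": data}, "+", LIB)
        minus = make_track({"chr1": {}}, "-", LIB)
        genic = [GenomicInterval("chr1", 2 * W + 100, 2 * W + 200)]
        assert call_intergenic_pics(
            plus, minus, chrom_sizes={"chr1": 60_000},
            genic_intervals=genic, genic_mode="drop",
        ) == []


class TestSyntenyAnchor:
    def _cluster(self, start, end):
        return IntergenicPiC(GenomicInterval("chr1", start, end), 20, 20, 0)

    def test_anchor_translates_to_reference_names(self):
        omap = OrthologMap()
        for sp, prefix in (("mouse", "m"), ("dog", "d")):
            omap.add(sp, f"{prefix}_ccar1", "CCAR1")
            omap.add(sp, f"{prefix}_ddx50", "DDX50")
        keys = {}
        for sp, prefix in (("mouse", "m"), ("dog", "d")):
            genes = [
                simple_gene(f"{prefix}_ccar1", start=1000),
                simple_gene(f"{prefix}_ddx50", start=50_000),
            ]
            anchor = anchor_by_synteny(
                self._cluster(10_000, 20_000), genes, omap, sp
            )
            keys[sp] = anchor.key
        assert keys["mouse"] == keys["dog"] == "CCAR1|DDX50"

    def test_one_sided_anchor_flagged(self):
        genes = [simple_gene("g", start=1000)]
        anchor = anchor_by_synteny(self._cluster(10_000, 20_000), genes)
        assert anchor.one_sided
        assert anchor.downstream == "*"

    def test_far_gene_beyond_max_dist_ignored(self):
        genes = [simple_gene("g", start=5_000_000)]
        anchor = anchor_by_synteny(
            self._cluster(10_000, 20_000), genes, max_anchor_dist=1_000_000
        )
        assert anchor.one_sided

    def test_anchor_key_invariant_to_gene_order(self):
        genes = [simple_gene("up", start=1000), simple_gene("down", start=50_000)]
        a = anchor_by_synteny(self._cluster(10_000, 20_000), genes)
        b = anchor_by_synteny(self._cluster(10_000, 20_000), list(reversed(genes)))
        assert a.key == b.key == "up|down"
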