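"""Repertoire overlap partitions, similarity criteria, tests, ECpiC classes."""
import math

import numpy as np
import pandas as pd
import pytest

from picluster import (
    build_repertoire_table, classify_conservation, compare_partitions,
    expression_overlap, pic_overlap, two_proportion_z,
)
from picluster.crossspecies import VennPartition


def table(data, species=("s1", "s2", "s3")):
    return pd.DataFrame(data, columns=list(species))


class TestPicOverlap:
    def test_threshold_assigns_subset(self):
        t = table({"s1": [15.0], "s2": [12.0], "s3": [0.0]}).set_axis(["L1"])
        part = pic_overlap(t, 10)
        assert part.assignments["L1"] == frozenset({"s1", "s2"})

    def test_stringent_mode_shrinks_subsets(self):
        t = table({"s1": [15.0], "s2": [12.0], "s3": [0.0]}).set_axis(["L1"])
        loose = pic_overlap(t, 10).assignments["L1"]
        strict = pic_overlap(t, 20).assignments
        assert "L1" not in strict or strict["L1"] <= loose

    def test_absent_distinct_from_zero(self):
        t = pd.DataFrame({"s1": [15.0, 15.0], "s2": [0.0, np.nan]},
                         index=["a", "b"])
        part = pic_overlap(t, 10)
        assert part.assignments["a"] == frozenset({"s1"})
        assert part.assignments["b"] == frozenset({"s1"})

    def test_counts_sum_to_total_loci(self, rng):
        vals = rng.uniform(0, 40, size=(500, 3))
        t = pd.DataFrame(vals, columns=["s1", "s2", "s3"],
                         index=[f"L{i}" for i in range(500)])
        part = pic_overlap(t, 10)
        n_expressed = int((vals >= 10).any(axis=1).sum())
        assert part.total == n_expressed
        assert sum(part.subset_counts.values()) == n_expressed

    def test_monotone_in_threshold(self, rng):
        vals = rng.uniform(0, 40, size=(300, 3))
        t = pd.DataFrame(vals, columns=["s1", "s2", "s3"],
                         index=[f"L{i}" for i in range(300)])
        lo = pic_overlap(t, 10).assignments
        hi = pic_overlap(t, 20).assignments
        for locus, subset in hi.items():
            assert subset <= lo[locus]

    def test_equals_bruteforce_set_algebra(self, rng):
        vals = rng.uniform(0, 40, size=(1000, 3))
        species = ["s1", "s2", "s3"]
        t = pd.DataFrame(vals, columns=species,
                         index=[f"L{i}" for i in range(1000)])
        part = pic_overlap(t, 10)
        # oracle: per-species sets, then explicit intersection/difference algebra
        above = {sp: set(t.index[t[sp] >= 10]) for sp in species}
        from itertools import combinations
        for r in (1, 2, 3):
            for combo in combinations(species, r):
                inside = set(t.index)
                for sp in combo:
                    inside &= above[sp]
                for sp in species:
                    if sp not in combo:
                        inside -= above[sp]
                assert part.subset_counts.get(frozenset(combo), 0) == len(inside)

    def test_repertoire_table_roots_species_columns(self):
        t = build_repertoire_table(
            {"mouse": {"Asb1": 50.0}, "human": {"Asb1": 40.0, "Cbl": 12.0}}
        )
        assert set(t.columns) == {"mouse", "human"}
        assert math.isnan(t.loc["Cbl", "mouse"])  # absent, not zero


class TestExpressionOverlap:
    def test_pair_within_default_delta(self):
        t = pd.DataFrame({"s1": [100.0], "s2": [250.0]}, index=["g"])
        part = expression_overlap(t, pair_delta=0.5)
        # |log10(100) - log10(250)| = 0.398 <= 0.5
        assert part.assignments["g"] == frozenset({"s1", "s2"})

    def test_same_pair_fails_stringent_delta(self):
        t = pd.DataFrame({"s1": [100.0], "s2": [250.0]}, index=["g"])
        part = expression_overlap(t, pair_delta=0.3)
        assert part.assignments["g"] == frozenset({"s2"})  # higher-expression singleton

    def test_identical_triple_shared_in_all_modes(self):
        t = pd.DataFrame({"s1": [100.0], "s2": [100.0], "s3": [100.0]},
                         index=["g"])
        for sd in (0.3, 0.177):
            part = expression_overlap(t, triple_sd=sd)
            assert part.assignments["g"] == frozenset({"s1", "s2", "s3"})

    def test_tenfold_spread_not_triple_shared(self):
        t = pd.DataFrame({"s1": [10.0], "s2": [100.0], "s3": [1000.0]},
                         index=["g"])
        part = expression_overlap(t, triple_sd=0.3)
        # sample SD of log10 = 1.0 > 0.3
        assert part.assignments["g"] != frozenset({"s1", "s2", "s3"})

    def test_zero_expression_treated_as_absent(self):
        t = pd.DataFrame({"s1": [0.0], "s2": [100.0], "s3": [110.0]},
                         index=["g"])
        part = expression_overlap(t)
        assert part.assignments["g"] == frozenset({"s2", "s3"})

    def test_counts_conserved(self, rng):
        vals = 10 ** rng.uniform(0, 3, size=(200, 3))
        t = pd.DataFrame(vals, columns=["s1", "s2", "s3"],
                         index=[f"g{i}" for i in range(200)])
        part = expression_overlap(t)
        assert part.total == 200
        assert sum(part.subset_counts.values()) == 200


class TestPartitionTests:
    def _partition(self, counts, species=("a", "b")):
        part = VennPartition(tuple(species))
        i = 0
        for subset, n in counts.items():
            for _ in range(n):
                part.assignments[f"x{i}"] = frozenset(subset)
                i += 1
        return part

    def test_identical_partitions_statistic_zero(self):
        p = self._partition({("a",): 30, ("b",): 20, ("a", "b"): 50})
        rep = compare_partitions(p, p)
        assert rep.chi2 == 0.0
        assert rep.chi2_p == 1.0

    def test_two_proportion_z_closed_form(self):
        # 30/100 vs 60/100, pooled p = 0.45
        z, p = two_proportion_z(30, 100, 60, 100)
        pooled = 0.45
        se = math.sqrt(pooled * (1 - pooled) * (1 / 100 + 1 / 100))
        z_expect = (0.30 - 0.60) / se
        assert z == pytest.approx(z_expect, abs=1e-10)
        assert z == pytest.approx(-4.264, abs=1e-3)
        assert p == pytest.approx(2.008e-5, rel=1e-3)

    def test_bonferroni_multiplies_and_caps(self):
        a = self._partition({("a",): 50, ("b",): 10, ("a", "b"): 40})
        b = self._partition({("a",): 30, ("b",): 30, ("a", "b"): 40})
        rep = compare_partitions(a, b)
        for _, row in rep.subset_tests.iterrows():
            assert row.p_bonferroni == pytest.approx(
                min(1.0, row.p_raw * rep.n_subsets_tested)
            )

    def test_chi2_matches_manual_contingency(self):
        a = self._partition({("a",): 30, ("b",): 20, ("a", "b"): 50})
        b = self._partition({("a",): 10, ("b",): 40, ("a", "b"): 50})
        rep = compare_partitions(a, b)
        obs = np.array([[30, 20, 50], [10, 40, 50]], dtype=float)
        row = obs.sum(axis=1, keepdims=True)
        col = obs.sum(axis=0, keepdims=True)
        expected = row @ col / obs.sum()
        chi2_manual = (((obs - expected) ** 2) / expected).sum()
        assert rep.chi2 == pytest.approx(chi2_manual, abs=1e-10)

    def test_low_expected_counts_fall_back_to_exact(self):
        a = self._partition({("a",): 200, ("a", "b"): 1})
        b = self._partition({("a",): 200})
        with pytest.warns(UserWarning, match="exact"):
            rep = compare_partitions(a, b)
        assert rep.subset_tests[rep.subset_tests.exact].shape[0] >= 1


class TestConservationClass:
    CLADES = {"human": "Primates", "mouse": "Glires", "dog": "Laurasiatherians"}

    def test_all_clades_expressed_is_ecpic(self):
        t = pd.DataFrame(
            {"human": [12.0], "mouse": [15.0], "dog": [30.0]}, index=["L"]
        )
        (call,) = classify_conservation(t, self.CLADES, 10)
        assert call.label == "ECpiC"

    def test_missing_clade_is_lcpic(self):
        t = pd.DataFrame(
            {"human": [12.0], "mouse": [15.0], "dog": [0.0]}, index=["L"]
        )
        (call,) = classify_conservation(t, self.CLADES, 10)
        assert call.label == "LCpiC"
        assert call.evidence["Laurasiatherians"] == 0

    def test_species_missing_from_clade_map_errors(self):
        t = pd.DataFrame({"human": [12.0], "cat": [1.0]}, index=["L"])
        with pytest.raises(ValueError, match="cat"):
            classify_conservation(t, {"human": "Primates"}, 10)
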