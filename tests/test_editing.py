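"""Hyper-edit transform, candidate screening, levels, clusters, stages."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lactovar import syndata
from lactovar.editing import (
    call_clusters,
    classify_candidate_read,
    cluster_summary,
    collapse_strand,
    compare_stages,
    detect_sites,
    editing_level,
    hyper_edit_transform,
    realign_transformed,
)


class TestTransform:
    def test_rule(self):
        assert hyper_edit_transform("AACGT") == "GGCGT"

    def test_no_a_is_identity(self):
        assert hyper_edit_transform("CCGGTT") == "CCGGTT"

    def test_idempotent(self):
        s = "ATTACGGTAN"
        assert hyper_edit_transform(hyper_edit_transform(s)) == hyper_edit_transform(s)

    def test_non_dna_rejected(self):
        with pytest.raises(ValueError):
            hyper_edit_transform("ACGU")


class TestRealign:
    REF = "CCGTACGTTAGCATCGATGCCATTGCGTACCGGATCAGTTCGAATCCGGA"

    def test_exact_substring_placed(self):
        read = self.REF[10:30]
        assert realign_transformed([read], self.REF, max_mismatch=0, seed_len=8) == [10]

    def test_editing_only_mismatches_vanish(self):
        read = list(self.REF[10:30])
        for i, b in enumerate(read):
            if b == "A":
                read[i] = "G"  # fully edited read
        placed = realign_transformed(["".join(read)], self.REF, max_mismatch=0, seed_len=8)
        assert placed == [10]

    def test_leftmost_tie_break(self):
        ref = "ACGTACGTACGTACGT"
        read = "ACGTACGT"
        assert realign_transformed([read], ref, max_mismatch=0, seed_len=4) == [0]

    def test_unplaceable_read_discarded(self):
        placed = realign_transformed(["TTTTTTTTTTTT"], "CACACACACACACACACACA", 0, seed_len=6)
        assert placed == [None]


class TestClassify:
    def _window(self, length, edits=(), others=()):
        ref = ("ACGT" * (length // 4 + 1))[:length]
        read = list(ref)
        n_edit = 0
        for i in range(length):
            if ref[i] == "A" and n_edit < len(edits):
                read[i] = "G"
                n_edit += 1
        n_other = 0
        for i in range(length):
            if ref[i] == "C" and n_other < len(others):
                read[i] = "T" if ref[i] != "T" else "A"
                n_other += 1
        return "".join(read), ref

    def test_long_read_five_percent_rule(self):
        read, ref = self._window(100, edits=range(5))
        ok, profile = classify_candidate_read(read, ref, np.full(100, 30))
        assert ok
        assert len(profile) == 5

    def test_short_read_needs_three(self):
        read, ref = self._window(50, edits=range(2))
        ok, _ = classify_candidate_read(read, ref, np.full(50, 30))
        assert not ok
        read3, ref3 = self._window(50, edits=range(3))
        ok3, _ = classify_candidate_read(read3, ref3, np.full(50, 30))
        assert ok3

    def test_dominance_rule(self):
        read, ref = self._window(100, edits=range(5), others=range(2))
        ok, profile = classify_candidate_read(read, ref, np.full(100, 30))
        assert len(profile) == 7
        assert not ok  # 5/7 <= 0.8

    def test_quality_filter(self):
        read, ref = self._window(100, edits=range(5))
        ok, _ = classify_candidate_read(read, ref, np.full(100, 20))
        assert not ok

    def test_homopolymer_filter(self):
        ref = "A" * 30 + ("ACGT" * 20)[:70]
        read = list(ref)
        edited = 0
        for i in range(30, 100):
            if ref[i] == "A" and edited < 5:
                read[i] = "G"
                edited += 1
        ok, _ = classify_candidate_read("".join(read), ref, np.full(100, 30))
        assert not ok  # 30-bp homopolymer run

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_pure_function_of_inputs(self, seed):
        rng = np.random.default_rng(seed)
        length = int(rng.integers(30, 120))
        ref = "".join(rng.choice(list("ACGT"), length))
        read = "".join(rng.choice(list("ACGTN"), length))
        quals = rng.integers(10, 41, length)
        out1 = classify_candidate_read(read, ref, quals)
        out2 = classify_candidate_read(read, ref, quals)
        assert out1 == out2


class TestEditingLevel:
    @pytest.mark.parametrize(
        "counts,expected", [((3, 2, 8), 0.5), ((0, 0, 20), 0.0), ((10, 0, 10), 1.0)]
    )
    def test_formula(self, counts, expected):
        assert editing_level(*counts) == pytest.approx(expected)

    def test_zero_denominator(self):
        assert editing_level(0, 0, 0) == 0.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            editing_level(-1, 0, 5)
        with pytest.raises(ValueError):
            editing_level(6, 0, 5)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50))
    def test_bounded_and_monotone(self, mg, ug, extra_depth):
        depth = mg + extra_depth
        lv = editing_level(mg, ug, depth)
        assert 0.0 <= lv <= 1.0
        if mg + 1 <= depth:
            assert editing_level(mg + 1, ug, depth) >= lv
        assert editing_level(mg, ug + 1, depth) >= lv


class TestCollapseStrand:
    def _sites(self, rows):
        return pd.DataFrame(
            rows,
            columns=["chrom", "pos", "ref_base", "alt_base", "mapped_G",
                     "unmapped_G", "mapped_depth"],
        )

    def test_tc_relabelled(self):
        out = collapse_strand(self._sites([("ref", 5, "T", "C", 2, 1, 10)]))
        assert list(out["type"]) == ["A-to-G"]

    def test_same_locus_merged(self):
        out = collapse_strand(
            self._sites(
                [("ref", 5, "A", "G", 4, 2, 10), ("ref", 5, "T", "C", 2, 1, 6)]
            )
        )
        assert len(out) == 1
        assert out.loc[0, "mapped_depth"] == 16
        assert out.loc[0, "mapped_G"] == 6

    def test_no_tc_identity(self):
        sites = self._sites([("ref", 1, "A", "G", 1, 1, 5)])
        out = collapse_strand(sites)
        assert len(out) == 1
        assert out.loc[0, "pos"] == 1


class TestClusters:
    def _frame(self, positions, chrom="ref"):
        return pd.DataFrame({"chrom": chrom, "pos": positions})

    def test_gap_chaining(self):
        clusters = call_clusters(self._frame([1, 50, 140, 300]))
        spans = [(c.start, c.end, c.n_sites) for c in clusters]
        assert spans == [(1, 140, 3), (300, 300, 1)]

    def test_boundary_inclusive_100(self):
        assert len(call_clusters(self._frame([0, 100]))) == 1
        assert len(call_clusters(self._frame([0, 101]))) == 2

    def test_chromosomes_never_merge(self):
        sites = pd.DataFrame(
            {"chrom": ["c1", "c2"], "pos": [0, 10]}
        )
        assert len(call_clusters(sites)) == 2

    def test_summary(self):
        clusters = call_clusters(self._frame([0, 50, 90, 500]))
        s = cluster_summary(clusters)
        assert s["n_clusters"] == 2
        assert s["mean_length"] == pytest.approx((91 + 1) / 2)
        assert s["mean_sites"] == pytest.approx(2.0)


class TestCompareStages:
    def _table(self, pos_levels):
        return pd.DataFrame(
            [
                {"chrom": "ref", "pos": p, "level": lv}
                for p, lv in pos_levels.items()
            ]
        )

    def test_specific_and_common_rules(self):
        tables = {
            "a1": self._table({10: 0.5, 20: 0.4}),
            "a2": self._table({10: 0.6, 20: 0.5}),
            "b1": self._table({20: 0.5, 30: 0.2}),
            "b2": self._table({20: 0.4, 30: 0.3}),
        }
        labels = {"a1": "lact", "a2": "lact", "b1": "dry", "b2": "dry"}
        out = compare_stages(tables, labels)
        assert out["stage_specific"]["lact"] == {("ref", 10)}
        assert out["stage_specific"]["dry"] == {("ref", 30)}
        assert out["common"] == {("ref", 20)}

    def test_planted_level_difference_flagged(self):
        rng = np.random.default_rng(0)
        tables, labels = {}, {}
        for g, base in (("lact", 0.2), ("dry", 0.8)):
            for i in range(6):
                s = f"{g}{i}"
                # binomial sampling noise at depth 50 around the stage level
                site_levels = {
                    10: rng.binomial(50, base) / 50,
                    30: rng.binomial(50, 0.5) / 50,
                }
                tables[s] = self._table(site_levels)
                labels[s] = g
        out = compare_stages(tables, labels)
        assert ("ref", 10) in out["differential"]
        assert ("ref", 30) not in out["differential"]

    def test_missing_group_rejected(self):
        tables = {"a1": self._table({1: 0.5}), "a2": self._table({1: 0.5})}
        with pytest.raises(ValueError):
            compare_stages(tables, {"a1": "x", "a2": "x"})


class TestDetection:
    def test_planted_site_recovery(self):
        ref, reads, truth = syndata.sim_edited_reads(
            ref_length=4000, n_sites=24, levels=[0.3, 0.5, 0.7], depth=50,
            read_length=60, error_rate=0.001, seed=17, sites_per_cluster=8,
        )
        sites = detect_sites(reads, ref)
        found = set(sites["pos"])
        planted = set(truth["pos"])
        sens = len(found & planted) / len(planted)
        prec = len(found & planted) / max(len(found), 1)
        assert sens >= 0.9
        assert prec >= 0.9

    def test_no_editing_no_sites(self):
        ref, reads, _ = syndata.sim_edited_reads(
            ref_length=1500, n_sites=4, levels=[0.0], depth=20,
            read_length=60, error_rate=0.0, seed=19,
        )
        sites = detect_sites(reads, ref)
        assert sites.empty
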