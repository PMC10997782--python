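"""Triple peaks, clustering, the D(S) assignment cascade, diversity stats."""

import re
from collections import defaultdict

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2_contingency

from acedup.hap_diversity import (
    HaplotypeRecord,
    assign_ds_copies,
    cluster_haplotypes,
    detect_triple_peaks,
    distinct_count_test,
    expected_het_freq,
    pairwise_divergence,
)
from acedup.synthetic_data import HaplotypeSimConfig, simulate_haplotype_population


def H(ind, label, seq, rc="S"):
    return HaplotypeRecord(ind, label, seq, rc)


class TestTriplePeaks:
    def test_three_bases_in_a_column_reported(self):
        assert detect_triple_peaks(["AAAA", "ACAA", "AGAA"]) == [1]

    def test_two_haplotypes_never_triple(self):
        assert detect_triple_peaks(["ACGT", "TGCA"]) == []

    def test_gaps_do_not_count_as_bases(self):
        assert detect_triple_peaks(["A-AA", "ACAA", "AGAA"]) == []

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            detect_triple_peaks(["AAA", "AAAA"])


class TestClustering:
    def test_identical_sequences_cluster(self):
        recs = [H("i1", "S1", "ACGT"), H("i2", "S1", "ACGT"), H("i3", "S1", "AAAA")]
        parts = cluster_haplotypes(recs)
        assert [len(c) for c in parts] == [2, 1]

    def test_all_distinct_gives_singletons(self):
        recs = [H(f"i{k}", "S1", "ACGT"[:3] + b) for k, b in enumerate("ACGT")]
        assert all(len(c) == 1 for c in cluster_haplotypes(recs))

    def test_r_haplotypes_excluded(self):
        recs = [H("i1", "R", "ACGT", "R"), H("i2", "S1", "ACGT")]
        parts = cluster_haplotypes(recs)
        assert parts == [["i2-S1"]]

    def test_order_independent(self):
        recs = [H(f"i{k}", "S1", s) for k, s in enumerate(["CC", "AA", "AA", "TT", "CC"])]
        a = cluster_haplotypes(recs)
        b = cluster_haplotypes(list(reversed(recs)))
        assert a == b


class TestAssignmentRules:
    """Small hand-built scenarios mirroring the published rule cascade."""

    SEQ = {
        "D1": "AAAA", "D2": "CCCC", "D3": "GGGG",
        "u1": "ATTT", "u2": "AGTT", "u3": "ACTT", "u4": "AATT",
    }

    def _population(self):
        S = self.SEQ
        return [
            # two D1 carriers (reference cluster) with distinct second haps
            H("a1", "S1", S["D1"]), H("a1", "S2", S["u1"]),
            H("a2", "S1", S["D1"]), H("a2", "S2", S["u2"]),
            # D2 cluster: three carriers
            H("b1", "S1", S["D2"]), H("b1", "S2", S["u3"]),
            H("b2", "S1", S["D2"]), H("b2", "S2", S["u4"]),
            # a DD heterozygote: one hap in D2 cluster, one in D3 cluster
            H("c1", "S1", S["D2"]), H("c1", "S2", S["D3"]),
            # second D3 carrier
            H("c2", "S1", S["D3"]), H("c2", "S2", "TTTT"),
            # undetermined: both haplotypes singletons
            H("d1", "S1", "TTAA"), H("d1", "S2", "TTCC"),
        ]

    def test_reference_match_labels_d1(self):
        state = assign_ds_copies(self._population(), {"D1(S)": self.SEQ["D1"]})
        assert state.labels["a1-S1"].label == "D1(S)"
        assert state.labels["a1-S1"].rule == "reference"
        assert state.genotype_calls["a1"] == "D1S"

    def test_multi_carrier_cluster_becomes_new_d(self):
        state = assign_ds_copies(self._population(), {"D1(S)": self.SEQ["D1"]})
        assert state.labels["b1-S1"].label == state.labels["b2-S1"].label
        assert state.labels["b1-S1"].label.startswith("D")
        assert state.labels["b1-S2"].label == "S"  # conservative default

    def test_four_copies_forces_dd_call(self):
        state = assign_ds_copies(
            self._population(), {"D1(S)": self.SEQ["D1"]}, {"c1": 4}
        )
        call = state.genotype_calls["c1"]
        assert re.fullmatch(r"D\d+D\d+", call), call

    def test_without_copy_info_dd_is_conservative_ds(self):
        state = assign_ds_copies(self._population(), {"D1(S)": self.SEQ["D1"]})
        assert state.genotype_calls["c1"].endswith("S")

    def test_three_copies_propagates_single_copy_identity(self):
        # e1 has 3 copies and its S1 sits in the better-supported cluster,
        # so its S2 is the single-copy S; S2 matches e2's S1, hence e2's
        # other hap must be a (new) D(S) even though it is a singleton
        S = self.SEQ
        recs = [
            H("e0", "S1", S["D2"]), H("e0", "S2", "ATAT"),
            H("e0b", "S1", S["D2"]), H("e0b", "S2", "ATCT"),
            H("e1", "S1", S["D2"]), H("e1", "S2", "GCGC"),
            H("e2", "S1", "GCGC"), H("e2", "S2", "CGCG"),
        ]
        state = assign_ds_copies(recs, {}, {"e1": 3})
        assert state.labels["e1-S2"].label == "S"
        assert state.labels["e2-S1"].label == "S"
        assert state.labels["e2-S2"].label.startswith("D")
        assert state.labels["e2-S2"].rule == "propagated-single-copy"

    def test_undetermined_pair_counts_one_new_allele(self):
        state = assign_ds_copies(self._population(), {"D1(S)": self.SEQ["D1"]})
        assert state.genotype_calls["d1"] == "undetermined"
        labels = {a.label for a in state.labels.values() if a.label.startswith("D")}
        # D1 + D2-cluster + D3-cluster labels, plus one undetermined carrier
        assert state.n_d_alleles == len(labels) + 1

    def test_contradictory_copy_info_flagged(self):
        recs = [H("x1", "S1", "AAAA"), H("x1", "R", "GGGG", "R")]
        state = assign_ds_copies(recs, {}, {"x1": 4})
        assert any("x1" in c for c in state.conflicts)


class TestAssignmentOnSimulations:
    @pytest.mark.parametrize("seed", range(6))
    def test_conservative_and_complete_on_multicarriers(self, seed):
        records, truth = simulate_haplotype_population(HaplotypeSimConfig(seed=seed))
        true_d, carriers = set(), defaultdict(set)
        for ind, g in truth.genotypes.items():
            for d in re.findall(r"D\d+", g):
                true_d.add(d)
                carriers[d].add(ind)
        state = assign_ds_copies(
            records, {"D1(S)": truth.ds_sequences["D1"]}, truth.copy_numbers
        )
        assert state.n_d_alleles <= len(true_d)
        seq2d = {v: k for k, v in truth.ds_sequences.items()}
        recovered = {
            seq2d[r.sequence]
            for r in records
            if r.sequence in seq2d
            and (a := state.labels.get(r.hap_id))
            and a.label not in ("S", "unassigned")
        }
        multi = {d for d in true_d if len(carriers[d]) >= 2}
        assert multi <= recovered

    @pytest.mark.parametrize("seed", range(6))
    def test_copy_info_never_decreases_allele_count(self, seed):
        records, truth = simulate_haplotype_population(HaplotypeSimConfig(seed=seed))
        without = assign_ds_copies(records, {"D1(S)": truth.ds_sequences["D1"]}, {})
        with_info = assign_ds_copies(
            records, {"D1(S)": truth.ds_sequences["D1"]}, truth.copy_numbers
        )
        assert with_info.n_d_alleles >= without.n_d_alleles

    def test_deterministic_under_input_permutation(self):
        records, truth = simulate_haplotype_population(HaplotypeSimConfig(seed=4))
        refs = {"D1(S)": truth.ds_sequences["D1"]}
        s1 = assign_ds_copies(records, refs, truth.copy_numbers)
        rng = np.random.default_rng(0)
        for _ in range(3):
            perm = list(records)
            rng.shuffle(perm)
            s2 = assign_ds_copies(perm, refs, truth.copy_numbers)
            # identical labels up to D_k renaming: compare the partition of
            # haplotype ids induced by each label
            def partition(state):
                groups = defaultdict(set)
                for hid, a in state.labels.items():
                    groups[a.label if a.label in ("S", "unassigned") else "D"].add(hid)
                bydlabel = defaultdict(set)
                for hid, a in state.labels.items():
                    if a.label not in ("S", "unassigned"):
                        bydlabel[a.label].add(hid)
                return groups, {frozenset(v) for v in bydlabel.values()}

            assert partition(s1) == partition(s2)
            assert s1.n_d_alleles == s2.n_d_alleles


class TestDistinctCountTest:
    def test_published_comparison(self):
        # 9/29 distinct D haplotypes vs 17/27 distinct S haplotypes
        chi2_stat, df, p = distinct_count_test(9, 29, 17, 27)
        assert round(chi2_stat, 1) == 4.5
        assert df == 1
        assert p == pytest.approx(0.03, abs=0.005)

    def test_equal_proportions_give_zero(self):
        stat, _, p = distinct_count_test(5, 10, 10, 20)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_extreme_difference_is_large(self):
        stat, _, p = distinct_count_test(0, 50, 50, 50)
        assert stat > 50 and p < 1e-10

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            distinct_count_test(5, 3, 1, 2)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.data())
    def test_matches_library_yates_chi_square(self, data):
        n1 = data.draw(st.integers(1, 30))
        n2 = data.draw(st.integers(1, 30))
        k1 = data.draw(st.integers(0, n1))
        k2 = data.draw(st.integers(0, n2))
        table = np.array([[k1, n1 - k1], [k2, n2 - k2]])
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            return
        stat, df, p = distinct_count_test(k1, n1, k2, n2)
        ref = chi2_contingency(table, correction=True)
        assert stat == pytest.approx(ref.statistic, abs=1e-9)
        assert p == pytest.approx(ref.pvalue, abs=1e-9)


class TestPairwiseDivergence:
    def test_single_difference(self):
        mask = [True] * 50 + [False] * 50
        res = pairwise_divergence(["A" * 100, "A" * 99 + "T"], mask)
        assert res.d == pytest.approx(0.01)
        assert res.d_exons == 0.0
        assert res.d_introns == pytest.approx(0.02)

    def test_identical_set_is_zero(self):
        res = pairwise_divergence(["ACGT" * 5] * 4, [True] * 20)
        assert res.d == 0.0

    def test_gap_columns_excluded_pairwise(self):
        res = pairwise_divergence(["AAT", "AA-", "AAC"], [True] * 3)
        # only the A/C comparison at the last site is informative
        assert res.d == pytest.approx((0 + 0 + 1 / 3) / 3)

    def test_intron_to_exon_ratio_matches_generator(self):
        cfg = HaplotypeSimConfig(seed=1)
        records, _ = simulate_haplotype_population(cfg)
        s_recs = [r for r in records if r.resistance_class == "S"]
        res = pairwise_divergence(s_recs, cfg.exon_mask())
        # intron rate triples the effective exonic rate
        assert 2.0 < res.d_introns / res.d_exons < 6.0
        assert res.d_exons == pytest.approx(0.008, abs=0.004)
        assert res.d_introns == pytest.approx(0.027, abs=0.01)


class TestExpectedHetFreq:
    @pytest.mark.parametrize(
        "fi, fj, same, expected",
        [(0.1, 0.2, False, 0.04), (0.0, 0.9, False, 0.0), (0.5, 0.5, True, 0.25)],
    )
    def test_panmixia_values(self, fi, fj, same, expected):
        assert expected_het_freq(fi, fj, same) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            expected_het_freq(1.2, 0.1)
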