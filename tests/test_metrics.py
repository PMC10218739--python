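"""Chance-corrected indices against exhaustive-enumeration oracles."""

from math import comb, log

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import spearmanr
from sklearn.metrics import adjusted_mutual_info_score

from shapescale import (
    PartitionPair,
    ami_max,
    ari_fnc,
    evaluation_report,
    expected_mi,
    expected_rand_index_fnc,
    mutual_information,
    pair_counts,
    rand_index,
    stirling2,
)
from shapescale.metrics import (
    DegenerateIndexError,
    cocluster_probability_fnc,
    log_stirling2,
)

import oracles


def pp(ref, obt):
    return PartitionPair.from_labels(ref, obt)


class TestPairCounts:
    def test_identical_partitions_have_no_false_pairs(self):
        p = pp([0, 0, 1, 2, 2], [5, 5, 1, 7, 7])
        pc = pair_counts(p)
        assert pc.FD == pc.FS == 0
        assert pc.TS + pc.TD == comb(5, 2)

    def test_crossed_four_sample_example(self):
        pc = pair_counts(pp([1, 1, 2, 2], [1, 2, 1, 2]))
        assert (pc.TS, pc.TD, pc.FD, pc.FS) == (0, 2, 2, 2)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(seed=st.integers(0, 10**6))
    def test_contingency_counts_match_pair_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 30))
        ref = rng.integers(0, 4, n)
        obt = rng.integers(0, 3, n)
        if len(np.unique(ref)) < 2 or len(np.unique(obt)) < 2:
            return
        pc = pair_counts(pp(ref, obt))
        assert tuple(pc) == oracles.pair_categories(ref, obt)
        assert sum(pc) == comb(n, 2)


class TestRandIndex:
    def test_examples_and_relabel_invariance(self, rng):
        assert rand_index(pp([0, 1, 1, 2], [0, 1, 1, 2])) == 1.0
        assert rand_index(pp([1, 1, 2, 2], [1, 2, 1, 2])) \
            == pytest.approx(2 / 6)
        obt = rng.integers(0, 3, 20)
        ref = rng.integers(0, 3, 20)
        relabeled = (obt + 1) % 3
        assert rand_index(pp(ref, obt)) == rand_index(pp(ref, relabeled))


class TestStirling:
    def test_boundaries_and_hand_value(self):
        assert stirling2(7, 1) == 1
        assert stirling2(7, 7) == 1
        assert stirling2(4, 2) == 7

    @pytest.mark.parametrize("n,C", [(6, 2), (8, 3), (10, 3)])
    def test_matches_exhaustive_partition_enumeration(self, n, C):
        assert stirling2(n, C) == oracles.stirling2_enumeration(n, C)

    def test_matches_sympy_on_a_grid(self):
        from sympy.functions.combinatorial.numbers import stirling

        for n in (5, 20, 60):
            for C in (1, 2, 3, 5):
                assert stirling2(n, C) == stirling(n, C, kind=2)

    def test_log_space_fallback_agrees_with_exact(self):
        for n, C in ((100, 3), (400, 2), (250, 4)):
            exact_log = log(stirling2(n, C))
            assert log_stirling2(n, C) == pytest.approx(exact_log, rel=1e-10)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            stirling2(3, 0)
        with pytest.raises(ValueError):
            stirling2(3, 4)


class TestARIfnc:
    def test_identical_partitions_score_one(self):
        assert ari_fnc(pp([0, 0, 1, 1, 2], [4, 4, 0, 0, 9])) \
            == pytest.approx(1.0)

    @pytest.mark.parametrize("n,C", [(6, 2), (7, 2), (8, 2), (6, 3), (8, 3)])
    def test_expected_ri_equals_enumeration_mean(self, n, C, rng):
        ref = rng.integers(0, 3, n)
        while len(np.unique(ref)) < 2:
            ref = rng.integers(0, 3, n)
        # formula uses only n, C and the reference co-cluster rate, so any
        # C-cluster obtained labeling yields the same E_fnc[RI]
        obt = np.arange(n) % C
        formula = expected_rand_index_fnc(pp(ref, obt))
        assert formula == pytest.approx(
            oracles.mean_rand_index_fnc(tuple(ref), C), abs=1e-12)

    def test_enumeration_mean_counts_all_partitions(self):
        # the n=6, C=2 null has exactly S(6,2) = 31 equiprobable partitions
        assert len(oracles.partitions_into_blocks(6, 2)) == 31

    def test_negative_when_ri_below_expectation(self):
        assert ari_fnc(pp([0, 0, 1, 1], [0, 1, 0, 1])) < 0

    def test_relabel_invariance(self, rng):
        ref = rng.integers(0, 3, 25)
        obt = rng.integers(0, 3, 25)
        perm = np.array([2, 0, 1])
        assert ari_fnc(pp(ref, obt)) == pytest.approx(
            ari_fnc(pp(perm[ref], perm[obt])))


class TestMutualInformation:
    def test_identical_partitions(self):
        m = mutual_information(pp([0, 0, 1, 1, 2, 2], [1, 1, 0, 0, 5, 5]))
        assert m.h_ref == pytest.approx(m.h_obt)
        assert m.h_joint == pytest.approx(m.h_ref)
        assert m.mi == pytest.approx(m.h_ref)

    def test_product_partitions_have_zero_mi(self):
        ref = [0, 0, 1, 1] * 3
        obt = [0, 1] * 6
        assert mutual_information(pp(ref, obt)).mi == pytest.approx(0, abs=1e-12)

    def test_matches_plugin_oracle(self, rng):
        ref = rng.integers(0, 4, 30)
        obt = rng.integers(0, 3, 30)
        assert mutual_information(pp(ref, obt)).mi == pytest.approx(
            oracles.plugin_mi(ref, obt), abs=1e-12)


class TestExpectedMI:
    def test_trivial_partitions_give_zero(self):
        ref = [0, 0, 0, 1]
        assert expected_mi(pp([0] * 4, [1] * 4)) == pytest.approx(0, abs=1e-14)

    @pytest.mark.parametrize("ref,obt", [
        ((0, 0, 1, 1), (0, 1, 0, 1)),
        ((0, 0, 1, 1), (0, 0, 1, 1)),
        ((0, 0, 0, 1, 1, 2), (0, 1, 2, 0, 1, 1)),
        ((0, 1, 1, 1, 2, 2), (0, 0, 1, 1, 2, 2)),
    ])
    def test_matches_exhaustive_permutation_mean(self, ref, obt):
        assert expected_mi(pp(ref, obt)) == pytest.approx(
            oracles.permutation_mean_mi(ref, obt), abs=1e-12)

    def test_bounded_by_min_entropy(self, rng):
        for _ in range(50):
            n = int(rng.integers(6, 25))
            p = pp(rng.integers(0, 3, n), rng.integers(0, 4, n))
            m = mutual_information(p)
            assert expected_mi(p) <= min(m.h_ref, m.h_obt) + 1e-12


class TestAMImax:
    def test_identical_partitions_score_one(self):
        assert ami_max(pp([0, 1, 1, 2, 2], [3, 0, 0, 1, 1])) \
            == pytest.approx(1.0)

    def test_invariant_to_log_base(self, rng):
        # recompute the ratio in base 2 by hand; it must agree
        ref = rng.integers(0, 3, 20)
        obt = rng.integers(0, 3, 20)
        p = pp(ref, obt)
        m = mutual_information(p)
        emi = expected_mi(p)
        ln2 = log(2.0)
        base2 = (m.mi / ln2 - emi / ln2) / (max(m.h_ref, m.h_obt) / ln2
                                            - emi / ln2)
        assert ami_max(p) == pytest.approx(base2, rel=1e-12)

    def test_agrees_with_sklearn_max_normalization(self, rng):
        for _ in range(20):
            n = int(rng.integers(8, 40))
            ref = rng.integers(0, 3, n)
            obt = rng.integers(0, 4, n)
            if len(np.unique(ref)) < 2 or len(np.unique(obt)) < 2:
                continue
            ours = ami_max(pp(ref, obt))
            theirs = adjusted_mutual_info_score(ref, obt,
                                                average_method="max")
            assert ours == pytest.approx(theirs, abs=1e-10)

    def test_can_be_negative(self, rng):
        found = False
        for seed in range(200):
            r = np.random.default_rng(seed)
            p = pp(r.integers(0, 2, 8), r.integers(0, 2, 8))
            try:
                if ami_max(p) < 0:
                    found = True
                    break
            except DegenerateIndexError:
                continue
        assert found

    def test_degenerate_denominator_raises(self):
        with pytest.raises(DegenerateIndexError):
            ami_max(pp([0] * 5, [1] * 5))


class TestReportAndAssociation:
    def test_report_is_consistent(self, rng):
        ref = rng.integers(0, 3, 30)
        obt = rng.integers(0, 3, 30)
        rep = evaluation_report(ref, obt)
        assert rep["TS"] + rep["TD"] + rep["FD"] + rep["FS"] == comb(30, 2)
        assert rep["ARI_fnc"] <= 1 and rep["AMI_max"] <= 1

    def test_indices_rank_correlate_across_partition_quality(self, rng):
        # degrade a reference progressively; the two indices must move together
        ref = np.repeat([0, 1, 2], 20)
        aris, amis = [], []
        for flip_frac in np.linspace(0.0, 0.8, 9):
            for _ in range(6):
                obt = ref.copy()
                k = int(flip_frac * ref.size)
                idx = rng.choice(ref.size, k, replace=False)
                obt[idx] = rng.integers(0, 3, k)
                if len(np.unique(obt)) < 3:
                    continue
                p = pp(ref, obt)
                aris.append(ari_fnc(p))
                amis.append(ami_max(p))
        rho, _ = spearmanr(aris, amis)
        assert rho > 0.9


def test_cocluster_probability_interpretation():
    # U for n=4, C=2: of the 7 two-block partitions, those keeping a fixed
    # pair together correspond to partitions of 3 items, S(3,2)=3
    assert cocluster_probability_fnc(4, 2) == pytest.approx(3 / 7)
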