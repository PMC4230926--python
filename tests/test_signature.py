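"""Substitution classes, dipyrimidine contexts and proportion tests."""

import numpy as np
import pytest
from scipy import stats

from melclone import (
    MutationRecord,
    context_fraction,
    detect_dinucleotide_mutations,
    expected_context_fraction,
    mutation_context,
    per_cluster_signature,
    proportion_test,
    substitution_class,
)
from melclone.signature import summarize


def mut(pos, ref, alt, sample="s", chrom="chr1"):
    return MutationRecord("P", sample, chrom, pos, ref, alt)


class TestSubstitutionClass:
    @pytest.mark.parametrize(
        "ref, alt, expected",
        [
            ("C", "T", "C>T"), ("G", "A", "C>T"),
            ("C", "A", "C>A"), ("G", "T", "C>A"),
            ("C", "G", "C>G"), ("G", "C", "C>G"),
            ("T", "A", "T>A"), ("A", "T", "T>A"),
            ("T", "C", "T>C"), ("A", "G", "T>C"),
            ("T", "G", "T>G"), ("A", "C", "T>G"),
        ],
    )
    def test_strand_collapse(self, ref, alt, expected):
        assert substitution_class(ref, alt) == expected

    def test_indel_rejected(self):
        with pytest.raises(ValueError):
            substitution_class("C", "CT")


class TestMutationContext:
    def test_pyrimidine_reference_read_directly(self):
        #        123456789012
        seq = "AAAAAAAATCAA"
        assert mutation_context(mut(10, "C", "T"), seq) == ("T", "A")

    def test_purine_reference_strand_flipped(self):
        seq = "AAAAAAAATGAA"
        # G at pos 10; opposite-strand C has 5' neighbor = revcomp(A)=T, 3' = revcomp(T)=A
        assert mutation_context(mut(10, "G", "A"), seq) == ("T", "A")

    def test_contig_edge_unavailable(self):
        assert mutation_context(mut(1, "C", "T"), "CTAA") is None
        assert mutation_context(mut(4, "A", "T"), "CTAA") is None

    def test_matches_naive_enumeration(self, uniform_reference):
        """Oracle: direct per-position string slicing with explicit complement."""
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        rng = np.random.default_rng(99)
        positions = rng.integers(2, len(uniform_reference) - 1, size=20)
        for pos in positions:
            ref_base = uniform_reference[pos - 1]
            alt = {"A": "G", "C": "T", "G": "A", "T": "C"}[ref_base]
            got = mutation_context(mut(int(pos), ref_base, alt), uniform_reference)
            left, right = uniform_reference[pos - 2], uniform_reference[pos]
            if ref_base in "CT":
                expected = (left, right)
            else:
                expected = (comp[right], comp[left])
            assert got == expected


class TestDinucleotideDetection:
    def test_adjacent_cc_to_tt(self):
        dnps, snvs = detect_dinucleotide_mutations([mut(100, "C", "T"), mut(101, "C", "T")])
        assert len(dnps) == 1 and snvs == []
        assert dnps[0].ref == "CC" and dnps[0].alt == "TT" and dnps[0].is_CCtoTT

    def test_gg_to_aa_counts_as_cc_tt(self):
        dnps, _ = detect_dinucleotide_mutations([mut(100, "G", "A"), mut(101, "G", "A")])
        assert dnps[0].is_CCtoTT

    def test_gap_of_two_not_merged(self):
        dnps, snvs = detect_dinucleotide_mutations([mut(100, "C", "T"), mut(102, "C", "T")])
        assert dnps == [] and len(snvs) == 2

    def test_different_samples_not_merged(self):
        dnps, snvs = detect_dinucleotide_mutations(
            [mut(100, "C", "T", "s1"), mut(101, "C", "T", "s2")]
        )
        assert dnps == [] and len(snvs) == 2

    def test_triple_run_merges_greedily(self):
        dnps, snvs = detect_dinucleotide_mutations(
            [mut(100, "C", "T"), mut(101, "C", "T"), mut(102, "C", "T")]
        )
        assert len(dnps) == 1 and dnps[0].pos == 100
        assert [m.pos for m in snvs] == [102]

    def test_brute_force_adjacency_scan(self):
        """3 adjacent pairs among 20 SNVs -> 3 DNPs, 14 SNVs remain."""
        positions = [100, 101, 200, 201, 300, 301] + list(range(1000, 1000 + 14 * 50, 50))
        muts = [mut(p, "C", "T") for p in positions]
        dnps, snvs = detect_dinucleotide_mutations(muts)
        assert len(dnps) == 3 and len(snvs) == 14
        # oracle: O(n^2) adjacency scan
        adjacent_pairs = {
            (a, b) for a in positions for b in positions if b == a + 1
        }
        assert len(dnps) == len(adjacent_pairs)


class TestContextFraction:
    def test_all_preceded_by_t(self):
        seq = "ATCAATCAATCA"
        muts = [mut(p, "C", "T") for p in (3, 7, 11)]
        k, n, frac = context_fraction(muts, seq, "prev")
        assert (k, n, frac) == (3, 3, 1.0)

    def test_hand_enumerated_fraction(self):
        # 10 C>T mutations, exactly 6 with pyrimidine 5' neighbor
        seq = "A" + "TCA" * 6 + "ACA" * 4 + "A"  # C at 3,6,...: first 6 preceded by T, next 4 by A
        positions = [3 * i + 3 for i in range(10)]
        muts = [mut(p, "C", "T") for p in positions]
        k, n, frac = context_fraction(muts, seq, "prev")
        assert (k, n, frac) == (6, 10, 0.6)

    def test_strand_collapsed_g_counts(self):
        # G>A with purine 3' reference neighbor: the opposite-strand mutated C
        # is preceded by a pyrimidine (complement of the purine)
        seq = "AAAAGAAA"  # 3' neighbor A -> collapsed prev = T (pyrimidine)
        k, n, frac = context_fraction([mut(5, "G", "A")], seq, "prev")
        assert (k, n, frac) == (1, 1, 1.0)
        seq2 = "AAAAGTAA"  # 3' neighbor T -> collapsed prev = A (purine)
        k2, n2, _ = context_fraction([mut(5, "G", "A")], seq2, "prev")
        assert (k2, n2) == (0, 1)
        seq3 = "AAAAGGAA"  # 3' neighbor G -> collapsed prev = C (pyrimidine)
        k3, n3, frac3 = context_fraction([mut(5, "G", "A")], seq3, "prev")
        assert (k3, n3, frac3) == (1, 1, 1.0)

    def test_empty_class_undefined(self):
        _, n, frac = context_fraction([mut(5, "T", "A")], "AAAATAAA", "prev")
        assert n == 0 and frac is None


class TestExpectedContextFraction:
    def test_alternating_tc_is_one(self):
        assert expected_context_fraction("TCTCTCTC", "prev") == 1.0

    def test_exhaustive_scan_on_repeated_acgt(self):
        seq = "ACGT" * 1000
        # oracle: literal per-position enumeration
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        k = n = 0
        for i in range(1, len(seq) - 1):
            b = seq[i]
            if b == "C":
                n += 1
                k += seq[i - 1] in "CT"
            elif b == "G":
                n += 1
                k += comp[seq[i + 1]] in "CT"
        assert expected_context_fraction(seq, "prev") == pytest.approx(k / n)

    def test_random_reference_approaches_half(self, uniform_reference):
        assert expected_context_fraction(uniform_reference, "prev") == pytest.approx(0.5, abs=0.01)
        assert expected_context_fraction(uniform_reference, "next") == pytest.approx(0.5, abs=0.01)

    def test_no_cg_rejected(self):
        with pytest.raises(ValueError):
            expected_context_fraction("ATATATAT", "prev")


class TestProportionTest:
    def test_null_is_nonsignificant(self):
        assert proportion_test(50, 100, 0.5) >= 0.99

    def test_extreme_case(self):
        assert proportion_test(1000, 1000, 0.5) < 1e-15

    def test_agrees_with_exact_binomial(self):
        approx = proportion_test(60, 100, 0.5)
        exact = stats.binomtest(60, 100, 0.5).pvalue
        assert abs(approx - exact) / exact < 0.10

    def test_small_expected_count_uses_exact(self):
        # n*p0 = 0.5 < 5 -> exact binomial branch
        assert proportion_test(2, 50, 0.01) == pytest.approx(
            stats.binomtest(2, 50, 0.01).pvalue
        )

    def test_zero_n_rejected(self):
        with pytest.raises(ValueError):
            proportion_test(0, 0, 0.5)


class TestPerClusterSignature:
    def test_single_cluster_equals_pooled(self, uniform_reference):
        muts = [mut(p, "C", "T") for p in (50, 150, 250) if uniform_reference[p - 1] == "C"]
        muts = muts or [mut(uniform_reference.index("C", 10) + 1, "C", "T")]
        res = per_cluster_signature(muts, [list(range(len(muts)))], uniform_reference)
        cluster, pooled = res[0], res[-1]
        assert cluster.class_counts == pooled.class_counts
        assert cluster.frac_prev_pyrimidine == pooled.frac_prev_pyrimidine

    def test_partition_conserves_class_counts(self, uniform_reference):
        rng = np.random.default_rng(5)
        positions = rng.choice(np.arange(2, 50_000), size=60, replace=False)
        muts = []
        for p in positions:
            ref_base = uniform_reference[p - 1]
            alt = {"A": "G", "C": "T", "G": "A", "T": "C"}[ref_base]
            muts.append(mut(int(p), ref_base, alt))
        half = len(muts) // 2
        res = per_cluster_signature(
            muts, [list(range(half)), list(range(half, len(muts)))], uniform_reference
        )
        summed = {
            cls: res[0].class_counts[cls] + res[1].class_counts[cls]
            for cls in res[0].class_counts
        }
        assert summed == res[-1].class_counts

    def test_pooled_fraction_between_cluster_fractions(self, uniform_reference):
        """A UV founding clone pooled with a larger non-UV subclone lands
        strictly between the two cluster fractions (the masking effect)."""
        from melclone import simulate_mutations
        from conftest import hypermutator_like_config

        cfg = hypermutator_like_config(seed=31)
        muts = simulate_mutations(cfg, uniform_reference)
        founding = [i for i, m in enumerate(muts) if m.clone_id == "founding"]
        subclone = [i for i, m in enumerate(muts) if m.clone_id == "subclone"]
        res = per_cluster_signature(muts, [founding, subclone], uniform_reference)
        f, s, pooled = (r.frac_prev_pyrimidine for r in res)
        assert min(f, s) < pooled < max(f, s)

    def test_empty_cluster_flagged(self, uniform_reference):
        muts = [mut(5, "T", "A")]
        res = summarize(muts, uniform_reference)
        assert res.frac_prev_pyrimidine is None and res.p_prev is None
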