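"""Canonical k-mer counting, per-hexamer statistics and the selection logic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from imescan.annotation_io import IntronRecord
from imescan.kmer_stats import (
    KmerCountTable,
    bh_fdr,
    canonical_kmer,
    canonical_table,
    count_kmers,
    entropy_empirical_pvalue,
    n_canonical,
    positional_contrast_test,
    positional_entropy,
    positional_profiles,
    relative_frequency,
    conservation_rate,
    select_candidates,
)

from ._oracles import brute_force_kmer_counts, rc, step_up_bh


def _intron(seq, first=True, gene="g", rank=1):
    return IntronRecord(
        gene_id=gene,
        transcript_id=f"{gene}.1",
        chrom="c",
        start=0,
        end=len(seq),
        strand="+",
        rank=rank,
        is_first=first,
        sequence=seq,
    )


class TestCanonical:
    def test_lexicographic_minimum(self):
        assert canonical_kmer("AAATCG") == "AAATCG"
        assert canonical_kmer("CGATTT") == "AAATCG"

    def test_palindrome_is_self(self):
        assert canonical_kmer("GAATTC") == "GAATTC"

    def test_n_is_uncountable(self):
        assert canonical_kmer("AANTCG") is None

    def test_class_count_formula(self):
        # (4^k + 4^(k/2)) / 2 for even k
        assert n_canonical(6) == 2080
        assert n_canonical(2) == 10

    def test_involution_over_all_hexamers(self):
        kmers, _ = canonical_table(6)
        for km in kmers[:200]:
            assert canonical_kmer(rc(km)) == km


class TestCountKmers:
    def test_single_window_homopolymer(self):
        table = count_kmers([_intron("A" * 12)], k=6, trim=3)
        assert table.count_first[table.index_of("AAAAAA")] == 1
        assert table.total_first == 1

    def test_mask_in_only_window_zeroes_masked_count(self):
        rec = _intron("A" * 12)
        masked = {"g|1": "AAAAA*AAAAAA"}
        table = count_kmers([rec], k=6, trim=3, masked_sequences=masked)
        i = table.index_of("AAAAAA")
        assert table.count_first[i] == 1
        assert table.masked_first[i] == 0

    def test_trim_zero_enumeration(self):
        table = count_kmers([_intron("ACGTACGT")], k=6, trim=0)
        assert table.total_first == 3  # ACGTAC, CGTACG, GTACGT

    def test_too_short_contributes_nothing(self):
        table = count_kmers([_intron("ACGTACGTACG")], k=6, trim=3)  # 11 < 2*3+6
        assert table.total_first == 0

    def test_matches_brute_force_oracle(self, small_corpus):
        paths, _ = small_corpus
        from imescan.pipeline import load_introns

        introns, _ = load_introns(paths["gff"], paths["genome"])
        first = [r for r in introns if r.is_first][:40]
        table = count_kmers(first, k=6, trim=3)
        oracle = brute_force_kmer_counts([r.sequence for r in first], k=6, trim=3)
        ours = {
            km: int(c)
            for km, c in zip(table.kmers, table.count_first)
            if c > 0
        }
        assert ours == oracle


class TestRelativeFrequency:
    def _table(self, cf, co):
        kmers, _ = canonical_table(2)
        cf = np.asarray(cf)
        co = np.asarray(co)
        return KmerCountTable(2, kmers, cf, co, cf.copy(), co.copy())

    def test_equal_counts_give_unit_ratio(self):
        c = np.arange(1, 11)
        f = relative_frequency(self._table(c, c))
        assert np.allclose(f, 1.0)

    def test_direct_arithmetic(self):
        cf = np.array([2] + [8] + [0] * 8)
        co = np.array([1] + [9] + [0] * 8)
        f = relative_frequency(self._table(cf, co))
        assert f[0] == pytest.approx(2.0)

    def test_scaling_invariance(self):
        cf = np.arange(1, 11)
        co = np.arange(10, 0, -1)
        f1 = relative_frequency(self._table(cf, co))
        f2 = relative_frequency(self._table(cf * 2, co))
        assert np.allclose(f1, f2)

    def test_label_exchange_inverts(self):
        cf = np.arange(1, 11)
        co = np.arange(10, 0, -1)
        f = relative_frequency(self._table(cf, co))
        finv = relative_frequency(self._table(co, cf))
        assert np.allclose(f, 1 / finv)

    def test_absent_in_other_set_is_inf(self):
        cf = np.array([2] + [8] + [0] * 8)
        co = np.array([0] + [10] + [0] * 8)
        f = relative_frequency(self._table(cf, co))
        assert np.isinf(f[0])

    def test_zero_total_is_hard_error(self):
        with pytest.raises(ValueError):
            relative_frequency(self._table(np.zeros(10, int), np.ones(10, int)))


def test_conservation_rate_unmasked_corpus_is_one():
    table = count_kmers([_intron("ACGTACGTACGT")], k=6, trim=0)
    ratio = conservation_rate(table, "first")
    observed = table.count_first > 0
    assert np.allclose(ratio[observed], 1.0)
    assert np.isnan(ratio[~observed]).all()


class TestEntropy:
    def test_degenerate_distribution(self):
        s, _ = positional_entropy(binned=[0, 12, 0, 0, 0, 0, 0, 0, 0, 0])
        assert s == 0.0

    def test_uniform_maximum(self):
        s, _ = positional_entropy(binned=[5] * 10)
        assert s == pytest.approx(np.log(10))

    def test_hand_computed_two_bins(self):
        s, _ = positional_entropy(binned=[3, 1])
        assert s == pytest.approx(0.5623, abs=1e-4)

    def test_raw_positions_are_binned(self):
        s, binned = positional_entropy([0.05, 0.15, 0.25, 0.95], bins=10)
        assert binned.tolist() == [1, 1, 1, 0, 0, 0, 0, 0, 0, 1]

    def test_pvalue_at_max_entropy_is_one(self):
        p = entropy_empirical_pvalue(np.log(10), 50, seed=0, n_sim=2000)
        assert p > 0.99

    def test_pvalue_floor_at_zero_entropy(self):
        p = entropy_empirical_pvalue(0.0, 1000, seed=0, n_sim=2000)
        assert p == pytest.approx(1 / 2001)

    def test_pvalue_monotone_in_observed_entropy(self):
        ps = [
            entropy_empirical_pvalue(s, 100, seed=42, n_sim=2000)
            for s in (0.5, 1.0, 1.5, 2.0, np.log(10))
        ]
        assert ps == sorted(ps)

    def test_null_pvalues_approximately_uniform(self):
        """Entropy p-values for truly uniform positions are ~U(0,1)."""
        rng = np.random.default_rng(3)
        pvals = []
        for _ in range(200):
            positions = rng.random(60)
            s, _ = positional_entropy(positions, bins=10)
            pvals.append(
                entropy_empirical_pvalue(s, 60, n_sim=1000, seed=rng)
            )
        assert sps.kstest(pvals, "uniform").pvalue > 0.01


class TestContrast:
    def test_identical_vectors_homogeneous(self):
        v = [10, 8, 12, 9, 11, 10, 10, 9, 11, 10]
        p = positional_contrast_test(v, v, n_sim=2000, seed=0)
        assert p > 0.5

    def test_disjoint_support_significant(self):
        a = [100] + [0] * 9
        b = [0] * 9 + [100]
        p = positional_contrast_test(a, b, n_sim=2000, seed=0)
        assert p < 1e-3

    def test_2x2_collapse_exact_hypergeometric(self):
        p = positional_contrast_test([5, 0], [0, 5])
        assert p == pytest.approx(2 / 252, rel=1e-9)

    def test_both_empty_undefined(self):
        assert np.isnan(positional_contrast_test([0] * 10, [0] * 10))

    @pytest.mark.parametrize(
        "a,b,exact_p",
        [
            # reference values from an exact network-algorithm Fisher test
            ([8, 1, 1], [1, 8, 1], 0.001970166),
            (
                [12, 3, 1, 9, 2, 8, 10, 4, 7, 7],
                [2, 11, 3, 9, 6, 8, 5, 2, 10, 4],
                0.02603255,
            ),
        ],
    )
    def test_monte_carlo_tracks_exact_rxc(self, a, b, exact_p):
        p_mc = positional_contrast_test(a, b, n_sim=100_000, seed=1)
        assert p_mc == pytest.approx(exact_p, abs=0.005)


class TestBhFdr:
    def test_forced_step_up(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_all_equal_unchanged(self):
        assert np.allclose(bh_fdr([0.1] * 5), 0.1)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    def test_matches_hand_rolled_step_up(self):
        rng = np.random.default_rng(5)
        p = rng.random(500)
        assert np.allclose(bh_fdr(p), step_up_bh(p))


class TestSelection:
    def _rows(self):
        return pd.DataFrame(
            {
                "cons_f": [0.99, 0.99, 0.90],
                "cons_o": [0.95, 0.95, 0.95],
                "F": [2.0, 0.9, 2.0],
                "q_entropy": [0.01, 0.01, 0.01],
                "q_contrast": [0.01, 0.01, 0.01],
            },
            index=["hit", "lowF", "lowcons"],
        )

    def test_conjunction_of_criteria(self):
        out = select_candidates(self._rows(), alpha=0.05)
        assert out.loc["hit", "candidate"]
        assert not out.loc["lowF", "candidate"]  # fails only criterion 2
        assert not out.loc["lowcons", "candidate"]

    def test_alpha_zero_empty(self):
        out = select_candidates(self._rows(), alpha=0.0)
        assert not out["candidate"].any()

    def test_candidate_count_monotone_in_alpha(self):
        rows = self._rows()
        n = [
            select_candidates(rows, alpha=a)["candidate"].sum()
            for a in (0.001, 0.02, 0.05, 0.5)
        ]
        assert n == sorted(n)

    def test_ties_fail_strict_inequalities(self):
        rows = self._rows()
        rows.loc["hit", "cons_f"] = rows.loc["hit", "cons_o"]
        assert not select_candidates(rows).loc["hit", "candidate"]

    def test_missing_statistics_excluded(self):
        rows = self._rows()
        rows.loc["hit", "q_entropy"] = np.nan
        assert not select_candidates(rows).loc["hit", "candidate"]


def test_profile_totals_match_counts(small_corpus):
    """Binned positional counts and the count table agree per k-mer."""
    paths, _ = small_corpus
    from imescan.pipeline import load_introns

    introns, _ = load_introns(paths["gff"], paths["genome"])
    table = count_kmers(introns, k=6, trim=3)
    bin_f, bin_o = positional_profiles(introns, k=6, trim=3)
    assert np.array_equal(bin_f.sum(axis=1), table.count_first)
    assert np.array_equal(bin_o.sum(axis=1), table.count_other)


class TestCanonicalProperties:
    hexamer = st.text(alphabet="ACGT", min_size=6, max_size=6)

    @given(hexamer)
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_canonicalization_is_idempotent_and_minimal(self, seq):
        canon = canonical_kmer(seq)
        assert canonical_kmer(canon) == canon
        assert canon <= seq
        assert canon == canonical_kmer(rc(seq))

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_bh_never_decreases_and_stays_in_unit_interval(self, pvals):
        q = bh_fdr(pvals)
        assert (q >= np.asarray(pvals) - 1e-12).all()
        assert (q <= 1.0 + 1e-12).all()
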