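"""Normalization, effect sizes, matched controls and the pentamer scorer."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from imescan.annotation_io import IntronRecord, split_first_other
from imescan.coexpression import (
    cohens_d,
    coexpression_effect,
    compare_to_imeter_set,
    expression_level_effect,
    filter_expressed_genes,
    imeter_like_score,
    matched_control_hexamers,
    motif_gene_set,
    pairwise_correlations,
    rank_by_imeter,
    read_expression_tsv,
    refine_candidates,
    train_pentamer_logodds,
    upper_quartile_normalize,
    PentamerLogOdds,
)
from imescan.kmer_stats import canonical_kmer, canonical_table, count_kmers, KmerCountTable
from imescan.pipeline import load_introns


class TestUpperQuartileNormalize:
    def test_scale_invariance_between_samples(self):
        rng = np.random.default_rng(0)
        a = rng.poisson(20, size=200).astype(float)
        counts = pd.DataFrame({"s1": a, "s2": 2 * a})
        out = upper_quartile_normalize(counts)
        assert np.allclose(out["s1"], out["s2"])

    def test_equal_upper_quartiles_after_normalization(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(
            {f"s{j}": rng.poisson(10 * (j + 1), size=300) for j in range(4)}
        ).astype(float)
        out = upper_quartile_normalize(counts)
        uq = [
            np.percentile(np.expm1(out[c])[np.expm1(out[c]) > 0], 75)
            for c in out.columns
        ]
        assert np.allclose(uq, uq[0])

    def test_all_zero_sample_rejected(self):
        counts = pd.DataFrame({"ok": [1.0, 2.0], "bad": [0.0, 0.0]})
        with pytest.raises(ValueError, match="bad"):
            upper_quartile_normalize(counts)


class TestFilterExpressedGenes:
    def _introns(self):
        return [
            IntronRecord("g1", "t", "c", 0, 50, "+", 1, is_first=True),
            IntronRecord("g2", "t", "c", 0, 50, "+", 1, is_first=True),
        ]

    def test_condition_threshold(self):
        expr = pd.DataFrame({"s1": [0.05, 1.5], "s2": [0.05, 1.5]}, index=["g1", "g2"])
        assert filter_expressed_genes(expr, self._introns(), "condition") == ["g2"]

    def test_gene_without_first_intron_excluded(self):
        expr = pd.DataFrame({"s1": [2.0, 2.0]}, index=["g1", "gX"])
        assert filter_expressed_genes(expr, self._introns(), "condition") == ["g1"]

    def test_accession_threshold(self):
        expr = pd.DataFrame({"s1": [0.5, 1.5], "s2": [0.5, 1.5]}, index=["g1", "g2"])
        assert filter_expressed_genes(expr, self._introns(), "accession") == ["g2"]


class TestCohensD:
    def test_identical_groups_zero(self):
        assert cohens_d([1, 2, 3], [1, 2, 3]).cohens_d == 0.0

    def test_hand_computed_pooled_sd(self):
        assert cohens_d([2, 4], [1, 3]).cohens_d == pytest.approx(1 / np.sqrt(2))

    def test_antisymmetry(self):
        d1 = cohens_d([2, 4, 5], [1, 3, 3]).cohens_d
        d2 = cohens_d([1, 3, 3], [2, 4, 5]).cohens_d
        assert d1 == pytest.approx(-d2)

    def test_zero_pooled_sd_undefined(self):
        assert np.isnan(cohens_d([1, 1], [1, 1]).cohens_d)


class TestPairwiseCorrelations:
    def test_identical_profiles_r_one(self):
        expr = pd.DataFrame([[1, 2, 3], [1, 2, 3]], index=["a", "b"])
        assert pairwise_correlations(expr, ["a", "b"])[0] == pytest.approx(1.0)

    def test_negated_profile_r_minus_one(self):
        expr = pd.DataFrame([[1, 2, 3], [-1, -2, -3]], index=["a", "b"])
        assert pairwise_correlations(expr, ["a", "b"])[0] == pytest.approx(-1.0)

    def test_pair_count_is_n_choose_2(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(rng.normal(size=(4, 10)), index=list("abcd"))
        assert len(pairwise_correlations(expr, list("abcd"))) == 6

    def test_subsampling_cap(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(rng.normal(size=(30, 10)))
        r = pairwise_correlations(expr, list(range(30)), max_pairs=100, seed=0)
        assert len(r) == 100


class TestMatchedControls:
    def _table(self, counts):
        kmers, _ = canonical_table(2)
        c = np.asarray(counts)
        return KmerCountTable(2, kmers, c, c.copy(), c.copy(), c.copy())

    def test_inclusive_ten_percent_bounds(self):
        counts = [100, 89, 90, 110, 111, 95, 200, 0, 50, 130]
        table = self._table(counts)
        target = table.kmers[0]
        out = matched_control_hexamers(target, table, tol=0.10)
        matched_counts = sorted(counts[table.kmers.index(k)] for k in out)
        assert matched_counts == [90, 95, 110]

    def test_tol_zero_exact_matches_only(self):
        counts = [100, 100, 99, 101, 100, 0, 0, 0, 0, 0]
        out = matched_control_hexamers(self._table(counts).kmers[0], self._table(counts), 0.0)
        assert len(out) == 2

    def test_target_never_returned(self):
        counts = [100] * 10
        table = self._table(counts)
        assert table.kmers[0] not in matched_control_hexamers(table.kmers[0], table)


class TestExpressionLevelEffect:
    def test_planted_shift_recovered(self):
        # per-gene baselines with unit variance; +1 shift for the set
        rng = np.random.default_rng(2)
        baseline = rng.normal(0, 1, size=1000)
        expr = pd.DataFrame(
            baseline[:, None] + rng.normal(0, 0.1, size=(1000, 20)),
            index=[f"g{i}" for i in range(1000)],
        )
        shifted = [f"g{i}" for i in range(100)]
        expr.loc[shifted] += 1.0
        res = expression_level_effect(shifted, expr)
        assert res.cohens_d == pytest.approx(1.0, abs=0.25)
        assert res.p < 1e-6

    def test_null_set_centered_on_zero(self):
        rng = np.random.default_rng(3)
        expr = pd.DataFrame(rng.normal(size=(1000, 30)), index=[f"g{i}" for i in range(1000)])
        sets = [list(rng.choice(expr.index, 50, replace=False)) for _ in range(20)]
        ds = [expression_level_effect(s, expr).cohens_d for s in sets]
        assert abs(np.mean(ds)) < 0.05

    def test_set_equal_background_zero(self):
        rng = np.random.default_rng(4)
        expr = pd.DataFrame(rng.normal(size=(50, 10)), index=[f"g{i}" for i in range(50)])
        assert expression_level_effect(expr.index, expr).cohens_d == 0.0


class TestPentamerScorer:
    def _introns(self, seqs, first=True):
        return [
            IntronRecord(f"g{i}", "t", "c", 0, len(s), "+", 1, is_first=first, sequence=s)
            for i, s in enumerate(seqs)
        ]

    def test_identical_corpora_zero_weights(self):
        seqs = ["ACGTACGTACGTACGT", "TTTTTCCCCCAAAAA"]
        w = train_pentamer_logodds(self._introns(seqs), self._introns(seqs))
        assert all(abs(v) < 1e-12 for v in w.weights.values())

    def test_proximal_only_pentamer_positive(self):
        prox = self._introns(["AAAAAAAGATCGAAAAAAA"] * 3)
        dist = self._introns(["TTTTTTTTTTTTTTTTTTT"] * 3, first=False)
        w = train_pentamer_logodds(prox, dist)
        assert w.weight("GATCG") > 0

    def test_doubling_corpora_leaves_weights(self):
        # exact invariance holds for observed pentamers once the
        # pseudocount is negligible against the counts
        prox = self._introns(["ACGTACGTACGTAAAT"] * 2)
        dist = self._introns(["TTGCATGCATGCATGC"] * 2, first=False)
        w1 = train_pentamer_logodds(prox, dist, pseudocount=1e-9)
        w2 = train_pentamer_logodds(prox * 2, dist * 2, pseudocount=1e-9)
        cp = {canonical_kmer(s[i : i + 5]) for s in ["ACGTACGTACGTAAAT"] for i in range(12)}
        cd = {canonical_kmer(s[i : i + 5]) for s in ["TTGCATGCATGCATGC"] for i in range(12)}
        for k in cp & cd:
            assert w1.weights[k] == pytest.approx(w2.weights[k], abs=1e-6)

    def test_zero_weights_score_zero(self):
        w = PentamerLogOdds({}, 1.0, 0, 0)
        assert imeter_like_score("ACGTACGTACGT", w) == 0.0

    def test_homogeneous_repeat_scores_linearly(self):
        canon = canonical_kmer("AAAAA")
        w = PentamerLogOdds({canon: 2.0}, 1.0, 0, 0)
        assert imeter_like_score("A" * 20, w) == pytest.approx((20 - 4) * 2.0)

    def test_additive_over_concatenation_up_to_boundary(self):
        rng = np.random.default_rng(0)
        weights = {
            km: float(rng.normal()) for km in canonical_table(5)[0]
        }
        w = PentamerLogOdds(weights, 1.0, 0, 0)
        a = "".join(rng.choice(list("ACGT"), 30))
        b = "".join(rng.choice(list("ACGT"), 30))
        joint = imeter_like_score(a + b, w)
        parts = imeter_like_score(a, w) + imeter_like_score(b, w)
        boundary = sum(
            w.weight((a + b)[i : i + 5]) for i in range(len(a) - 4, len(a))
        )
        assert joint == pytest.approx(parts + boundary)

    def test_planted_genes_rank_higher_by_score(self, small_corpus):
        """IMEter-style scores separate motif-planted genes (AUC > 0.9)."""
        paths, truth = small_corpus
        introns, _ = load_introns(paths["gff"], paths["genome"])
        first, other = split_first_other(introns)
        w = train_pentamer_logodds(first, other)
        ranking = rank_by_imeter(first, w)
        labels = ranking.index.isin(truth.motif_genes).astype(int)
        assert labels.sum() > 5
        # the > 0.9 separation property holds at the full default corpus
        # size (checked in the acceptance suite); this is the scaled corpus
        assert roc_auc_score(labels, ranking.to_numpy()) > 0.8


class TestCoexpressionEffect:
    def test_planted_latent_factor_detected(self, small_corpus):
        paths, truth = small_corpus
        introns, _ = load_introns(paths["gff"], paths["genome"])
        first, _ = split_first_other(introns)
        expr = read_expression_tsv(paths["expr_conditions"])
        table = count_kmers(introns)
        eff = coexpression_effect(
            truth.motif, expr, first, table, max_controls=15, seed=0
        )
        assert eff is not None and eff.mean_d > 0.2

    def test_null_hexamers_centered_on_zero(self, null_corpus):
        """Without planted co-expression, motif effects average to ~0."""
        paths, truth = null_corpus
        introns, _ = load_introns(paths["gff"], paths["genome"])
        first, _ = split_first_other(introns)
        expr = read_expression_tsv(paths["expr_conditions"])
        table = count_kmers(introns)
        rng = np.random.default_rng(0)
        counts = pd.Series(table.count_first, index=table.kmers)
        pool = counts[(counts > 50) & (counts < 400)].index.to_numpy()
        ds = []
        for km in rng.choice(pool, size=25, replace=False):
            eff = coexpression_effect(
                km, expr, first, table, max_controls=8, seed=rng
            )
            if eff is not None:
                ds.append(eff.mean_d)
        assert len(ds) >= 15
        assert abs(np.mean(ds)) < 0.05

    def test_single_control_mean_is_that_control(self):
        effects = {"m": None}
        assert refine_candidates(effects) == []

    def test_refinement_is_pure_threshold(self, small_corpus):
        class Eff:
            def __init__(self, d):
                self.mean_d = d

        effects = {"a": Eff(0.06), "b": Eff(0.05), "c": Eff(-0.2), "d": None}
        assert refine_candidates(effects, threshold=0.05) == ["a"]


def test_imeter_set_comparison_overlap_removal(small_corpus):
    paths, truth = small_corpus
    introns, _ = load_introns(paths["gff"], paths["genome"])
    first, other = split_first_other(introns)
    w = train_pentamer_logodds(first, other)
    ranking = rank_by_imeter(first, w)
    expr = read_expression_tsv(paths["expr_conditions"])
    genes = motif_gene_set(truth.motif, first)
    with_overlap = compare_to_imeter_set(genes, ranking, expr, seed=0)
    without = compare_to_imeter_set(genes, ranking, expr, remove_overlap=True, seed=0)
    assert np.isfinite(with_overlap.cohens_d) and np.isfinite(without.cohens_d)
    # removing shared (planted) genes from the IMEter set weakens that set's
    # internal correlation, so the motif set's relative effect cannot drop
    assert without.cohens_d >= with_overlap.cohens_d - 0.05
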