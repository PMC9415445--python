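"""Stage correlation, hypergeometric tails, list overlap, pathway enrichment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from reosig.enrichment import (
    combine_pair_lists,
    hypergeometric_tail,
    overlap_significance,
    pathway_enrichment,
    reo_indicator_matrix,
    stage_correlated_pairs,
)
from reosig.reo import A_GT_B, A_LT_B
from reosig.signature import Signature
from reosig.synthetic import (
    SimulationConfig,
    apply_monotone_distortion,
    simulate_signature_study,
    simulate_stage_cohort,
    truth_signature,
)
from reosig.scoring import score_cohort


class TestIndicatorMatrix:
    def test_noise_free_cancer_samples_all_ones(self):
        cfg = SimulationConfig(
            n_genes=30, n_planted_pairs=6, n_samples_per_group=4,
            noise_sd=0.0, distortion=False, seed=2,
        )
        _, _, test, truth = simulate_signature_study(cfg)
        sig = truth_signature(truth)
        ind = reo_indicator_matrix(test["cancer"], sig)
        assert (ind.to_numpy() == 1.0).all()
        assert (reo_indicator_matrix(test["normal"], sig).to_numpy() == 0.0).all()

    def test_invariant_under_distortion(self, rng):
        from tests.conftest import random_matrix

        matrix = random_matrix(rng, 20, 10)
        sig = Signature(pd.DataFrame({
            "gene_a": ["G0000", "G0002"], "gene_b": ["G0001", "G0003"],
            "normal_direction": [A_LT_B, A_GT_B],
            "cancer_direction": [A_GT_B, A_LT_B],
        }))
        before = reo_indicator_matrix(matrix, sig)
        after = reo_indicator_matrix(apply_monotone_distortion(matrix, seed=4), sig)
        pd.testing.assert_frame_equal(before, after)

    def test_column_sums_match_scores_for_tiefree_data(self, rng):
        from tests.conftest import random_matrix

        matrix = random_matrix(rng, 30, 8)
        pairs = pd.DataFrame({
            "gene_a": [f"G{i:04d}" for i in range(0, 10, 2)],
            "gene_b": [f"G{i:04d}" for i in range(1, 10, 2)],
        })
        pairs["normal_direction"] = A_LT_B
        pairs["cancer_direction"] = A_GT_B
        sig = Signature(pairs)
        ind = reo_indicator_matrix(matrix, sig)
        scores = [r.score for r in score_cohort(matrix, sig)]
        np.testing.assert_allclose(ind.sum(axis=0).to_numpy() / len(sig), scores)

    def test_unmeasured_pair_rows_are_missing(self):
        matrix = pd.DataFrame({"s": [1.0, 2.0]}, index=["A", "B"])
        sig = Signature(pd.DataFrame({
            "gene_a": ["A", "X"], "gene_b": ["B", "Y"],
            "normal_direction": [A_LT_B, A_LT_B],
            "cancer_direction": [A_GT_B, A_GT_B],
        }))
        ind = reo_indicator_matrix(matrix, sig)
        assert ind.iloc[1].isna().all()
        assert ind.iloc[0, 0] == 0.0


class TestStageCorrelatedPairs:
    def _indicator(self, rows, samples):
        frame = pd.DataFrame(rows, columns=samples)
        frame.index = pd.MultiIndex.from_tuples(
            [(f"A{i}", f"B{i}") for i in range(len(rows))], names=["gene_a", "gene_b"]
        )
        return frame

    def test_perfect_monotone_agreement(self):
        ind = self._indicator([[0, 0, 1, 1]], ["s1", "s2", "s3", "s4"])
        stages = pd.Series([1, 1, 2, 2], index=ind.columns)
        result = stage_correlated_pairs(ind, stages)
        assert result["rho"].iloc[0] == pytest.approx(1.0)

    def test_constant_indicator_excluded(self):
        ind = self._indicator([[1, 1, 1, 1], [0, 0, 1, 1]], list("wxyz"))
        stages = pd.Series([1, 1, 2, 2], index=ind.columns)
        result = stage_correlated_pairs(ind, stages)
        assert len(result) == 1

    def test_single_stage_level_rejected(self):
        ind = self._indicator([[0, 1, 0]], list("abc"))
        with pytest.raises(ValueError, match="stage"):
            stage_correlated_pairs(ind, pd.Series([1, 1, 1], index=ind.columns))

    def test_exact_permutation_matches_enumeration(self):
        # small two-level design: enumerate the full permutation null by hand
        from scipy import stats as sps

        x = np.array([0, 1, 0, 1, 1, 0], dtype=float)
        stages = np.array([1, 1, 1, 2, 2, 2], dtype=float)
        rho_obs = sps.spearmanr(x, stages).statistic
        rhos = []
        for perm in set(itertools.permutations(stages)):
            rhos.append(sps.spearmanr(x, np.array(perm)).statistic)
        expected = np.mean([abs(r) >= abs(rho_obs) - 1e-12 for r in rhos])
        ind = self._indicator([x], list("abcdef"))
        result = stage_correlated_pairs(
            ind, pd.Series(stages, index=ind.columns), exact_max_n=12
        )
        assert result["p_value"].iloc[0] == pytest.approx(expected)

    def test_null_cohort_bh_discoveries_controlled(self):
        cfg = SimulationConfig(
            n_genes=1100, n_planted_pairs=500, n_samples_per_group=30, seed=5
        )
        cohort = simulate_stage_cohort(cfg, (1, 2), (0.5, 0.5))
        sig = truth_signature(cohort.truth)
        ind = reo_indicator_matrix(cohort.matrix, sig)
        result = stage_correlated_pairs(ind, cohort.stages, 0.05)
        assert int(result["significant"].sum()) <= 0.05 * len(result) + 15

    def test_bh_qvalues_monotone_in_p_rank(self):
        rng = np.random.default_rng(10)
        ind = self._indicator(
            rng.integers(0, 2, size=(50, 40)).astype(float),
            [f"s{i}" for i in range(40)],
        )
        stages = pd.Series([1] * 20 + [2] * 20, index=ind.columns)
        result = stage_correlated_pairs(ind, stages)
        assert (result["q_value"].diff().dropna() >= -1e-12).all()


class TestHypergeometricTail:
    def test_reference_overlap_probability(self):
        assert hypergeometric_tail(2046, 33, 301, 8) == pytest.approx(0.0997, abs=5e-4)

    def test_k_zero_is_one(self):
        assert hypergeometric_tail(100, 10, 10, 0) == 1.0

    def test_complete_overlap_exact_rational(self):
        assert hypergeometric_tail(10, 5, 5, 5) == pytest.approx(1 / 252)

    def test_impossible_arguments_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_tail(10, 5, 5, 6)
        with pytest.raises(ValueError):
            hypergeometric_tail(10, 11, 5, 1)

    def test_nonincreasing_in_k(self):
        values = [hypergeometric_tail(50, 12, 20, k) for k in range(0, 13)]
        assert all(a >= b for a, b in zip(values, values[1:]))

    @pytest.mark.parametrize("N,m,n", [(12, 5, 6), (20, 8, 9), (15, 15, 4), (9, 3, 3)])
    def test_matches_exhaustive_enumeration(self, N, m, n):
        """Exact comparison against enumeration of all C(N, n) draws."""
        universe = list(range(N))
        marked = set(range(m))
        total = math.comb(N, n)
        for k in range(0, min(m, n) + 1):
            count = sum(
                1 for draw in itertools.combinations(universe, n)
                if len(marked.intersection(draw)) >= k
            )
            assert hypergeometric_tail(N, m, n, k) == pytest.approx(
                count / total, rel=1e-12
            )

    def test_agrees_with_scipy_survival_function(self):
        from scipy import stats as sps

        for N, m, n, k in [(2046, 33, 301, 8), (7838, 120, 368, 12), (500, 40, 60, 3)]:
            assert hypergeometric_tail(N, m, n, k) == pytest.approx(
                float(sps.hypergeom.sf(k - 1, N, m, n)), rel=1e-10
            )


class TestOverlapSignificance:
    def test_reference_lists(self):
        k, p = overlap_significance(
            [f"a{i}" for i in range(33)],
            [f"a{i}" for i in range(8)] + [f"b{i}" for i in range(293)],
            2046,
        )
        assert k == 8
        assert p == pytest.approx(0.0997, abs=5e-4)

    def test_disjoint_lists_p_one(self):
        _, p = overlap_significance(["x"], ["y"], 100)
        assert p == 1.0

    def test_identical_lists_minimal_p(self):
        lst = [f"g{i}" for i in range(5)]
        k, p = overlap_significance(lst, lst, 50)
        assert k == 5
        assert p == pytest.approx(1 / math.comb(50, 5), rel=1e-9)

    def test_list_exceeding_universe_rejected(self):
        with pytest.raises(ValueError):
            overlap_significance(list(range(20)), list(range(5)), 10)


class TestPathwayEnrichment:
    def test_exact_match_ranks_first(self):
        sets = {"target": {"g1", "g2", "g3"}, "other": {"h1", "h2", "h3", "g1"}}
        result = pathway_enrichment(["g1", "g2", "g3"], sets, N=1000)
        assert result.iloc[0]["set_name"] == "target"

    def test_zero_overlap_sets_omitted(self):
        sets = {"hit": {"g1"}, "misses": {"z1", "z2"}}
        result = pathway_enrichment(["g1"], sets, N=100)
        assert list(result["set_name"]) == ["hit"]

    def test_p_values_equal_hand_formula(self):
        # 20-gene universe, interested = 4 genes, set of 5 with k=2
        sets = {"S": {f"g{i}" for i in range(5)}}
        result = pathway_enrichment(["g0", "g1", "x1", "x2"], sets, N=20)
        expected = sum(
            math.comb(5, i) * math.comb(15, 4 - i) for i in range(2, 5)
        ) / math.comb(20, 4)
        assert result["p_value"].iloc[0] == pytest.approx(expected, rel=1e-12)

    def test_empty_gene_list_rejected(self):
        with pytest.raises(ValueError):
            pathway_enrichment([], {"S": {"g"}}, N=10)

    def test_uncorrected_mode_flags_on_raw_p(self):
        sets = {f"S{i}": {f"g{i}", f"h{i}"} for i in range(10)}
        genes = ["g0", "h0", "g1"]
        strict = pathway_enrichment(genes, sets, N=10000, fdr=0.05)
        loose = pathway_enrichment(genes, sets, N=10000, fdr=0.05, uncorrected=True)
        assert loose["significant"].sum() >= strict["significant"].sum()


class TestCombinePairLists:
    def test_union_arithmetic(self):
        shared = [(f"s{i}", f"t{i}") for i in range(8)]
        a = shared + [(f"a{i}", f"b{i}") for i in range(25)]
        b = shared + [(f"c{i}", f"d{i}") for i in range(293)]
        combined = combine_pair_lists(a, b)
        assert len(combined) == 326
        assert len(combined) == len(a) + len(b) - 8

    def test_disjoint_and_idempotent(self):
        a = [("a", "b"), ("c", "d")]
        b = [("e", "f"), ("g", "h"), ("i", "j")]
        assert len(combine_pair_lists(a, b)) == 5
        assert combine_pair_lists(a, a) == a
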