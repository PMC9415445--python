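"""Generator contracts: determinism, planted structure, noise behaviour."""

import numpy as np
import pandas as pd
import pytest

from reosig.reo import stable_pairs
from reosig.synthetic import (
    SimulationConfig,
    TreatmentConfig,
    apply_monotone_distortion,
    simulate_case_control,
    simulate_stage_cohort,
    simulate_treatment_study,
    truth_signature,
)
from reosig.de import two_group_stats
from reosig.scoring import score_cohort


def concordance_oracle(matrix: pd.DataFrame, truth: pd.DataFrame) -> list[float]:
    """Per-pair fraction of samples showing the normal ordering, counted by an
    independent per-sample loop."""
    fractions = []
    for row in truth.itertuples():
        a = matrix.loc[row.gene_a]
        b = matrix.loc[row.gene_b]
        wins = sum(
            (x > y) if row.normal_direction == "a_gt_b" else (x < y)
            for x, y in zip(a, b)
        )
        fractions.append(wins / matrix.shape[1])
    return fractions


class TestSimulateCaseControl:
    def test_same_seed_identical(self, small_config):
        c1 = simulate_case_control(small_config)
        c2 = simulate_case_control(small_config)
        for platform in c1.matrices:
            for phenotype in c1.matrices[platform]:
                pd.testing.assert_frame_equal(
                    c1.matrices[platform][phenotype], c2.matrices[platform][phenotype]
                )
        pd.testing.assert_frame_equal(c1.truth, c2.truth)

    def test_noise_free_pairs_fully_concordant(self):
        cfg = SimulationConfig(
            n_genes=40, n_planted_pairs=8, n_samples_per_group=12,
            noise_sd=0.0, distortion=False, seed=5,
        )
        cohort = simulate_case_control(cfg)
        for platform in cohort.matrices:
            normal = concordance_oracle(cohort.matrices[platform]["normal"], cohort.truth)
            assert normal == [1.0] * len(cohort.truth)
            cancer = concordance_oracle(cohort.matrices[platform]["cancer"], cohort.truth)
            assert cancer == [0.0] * len(cohort.truth)

    def test_concordance_decreases_with_noise(self):
        mean_conc = []
        for noise in (0.5, 1.0, 2.0, 4.0):
            cfg = SimulationConfig(
                n_genes=100, n_planted_pairs=25, n_samples_per_group=40,
                noise_sd=noise, distortion=False, seed=17,
            )
            cohort = simulate_case_control(cfg)
            conc = concordance_oracle(cohort.matrices["platform1"]["normal"], cohort.truth)
            mean_conc.append(np.mean(conc))
        assert all(a > b for a, b in zip(mean_conc, mean_conc[1:]))

    def test_pipeline_and_oracle_agree_on_stable_fraction(self):
        cfg = SimulationConfig(
            n_genes=200, n_planted_pairs=40, n_samples_per_group=30,
            distortion=False, seed=7,
        )
        cohort = simulate_case_control(cfg)
        matrix = cohort.matrices["platform1"]["normal"]
        oracle_frac = np.mean(
            [f >= 0.9 for f in concordance_oracle(matrix, cohort.truth)]
        )
        stable = stable_pairs(matrix, 0.9)
        keys = set(map(tuple, stable.pairs[["gene_a", "gene_b"]].to_numpy()))
        pipeline_frac = np.mean(
            [tuple(r) in keys for r in cohort.truth[["gene_a", "gene_b"]].to_numpy()]
        )
        assert pipeline_frac == oracle_frac

    def test_truth_pairs_use_disjoint_genes_present_on_platforms(self, small_config):
        cohort = simulate_case_control(small_config)
        members = list(cohort.truth["gene_a"]) + list(cohort.truth["gene_b"])
        assert len(members) == len(set(members))
        for gene in members:
            assert any(
                gene in groups["normal"].index for groups in cohort.matrices.values()
            )

    def test_platform_subsets_cover_requested_fraction(self):
        cfg = SimulationConfig(
            n_genes=200, n_planted_pairs=10, n_samples_per_group=5,
            platforms=(1.0, 0.5), seed=3,
        )
        cohort = simulate_case_control(cfg)
        assert cohort.matrices["platform1"]["normal"].shape[0] == 200
        n2 = cohort.matrices["platform2"]["normal"].shape[0]
        assert 100 <= n2 <= 120  # half the genome plus retained planted genes

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_genes=10, n_planted_pairs=6)
        with pytest.raises(ValueError):
            SimulationConfig(log_gap=0.0)
        with pytest.raises(ValueError):
            SimulationConfig(platforms=(1.5,))


class TestMonotoneDistortion:
    def test_square_example(self):
        matrix = pd.DataFrame({"s": [1.0, 2.0, 3.0]}, index=["a", "b", "c"])
        squared = matrix**2
        assert list(squared["s"].rank()) == list(matrix["s"].rank())

    def test_rank_vectors_identical(self, small_config):
        cohort = simulate_case_control(small_config)
        matrix = cohort.matrices["platform1"]["cancer"]
        distorted = apply_monotone_distortion(matrix, seed=42)
        for col in matrix.columns:
            assert np.array_equal(
                matrix[col].rank().to_numpy(), distorted[col].rank().to_numpy()
            )

    def test_rejects_nonpositive(self):
        bad = pd.DataFrame({"s": [0.0, 1.0]}, index=["a", "b"])
        with pytest.raises(ValueError):
            apply_monotone_distortion(bad, seed=0)

    def test_stable_pairs_unchanged_end_to_end(self, rng):
        from tests.conftest import random_matrix

        matrix = random_matrix(rng, 200, 30)
        distorted = apply_monotone_distortion(matrix, seed=11)
        pd.testing.assert_frame_equal(
            stable_pairs(matrix, 0.85).pairs, stable_pairs(distorted, 0.85).pairs
        )


class TestStageCohort:
    def test_extreme_probabilities_separate_stages(self):
        cfg = SimulationConfig(
            n_genes=60, n_planted_pairs=10, n_samples_per_group=10,
            distortion=False, seed=21,
        )
        cohort = simulate_stage_cohort(cfg, (1, 2), (0.0, 1.0), n_stage_pairs=10)
        sig = truth_signature(cohort.truth_stage_pairs)
        from reosig.enrichment import reo_indicator_matrix

        indicator = reo_indicator_matrix(cohort.matrix, sig)
        low = indicator.loc[:, cohort.stages == 1]
        high = indicator.loc[:, cohort.stages == 2]
        assert (low.to_numpy() == 0).all()
        assert (high.to_numpy() == 1).all()

    def test_decreasing_probabilities_rejected(self):
        cfg = SimulationConfig(n_genes=20, n_planted_pairs=4, seed=1)
        with pytest.raises(ValueError, match="nondecreasing"):
            simulate_stage_cohort(cfg, (1, 2), (0.8, 0.2))

    def test_null_cohort_rho_near_zero(self):
        cfg = SimulationConfig(
            n_genes=1100, n_planted_pairs=500, n_samples_per_group=50, seed=13
        )
        cohort = simulate_stage_cohort(cfg, (1, 2), (0.5, 0.5))
        from reosig.enrichment import reo_indicator_matrix, stage_correlated_pairs

        sig = truth_signature(cohort.truth)
        indicator = reo_indicator_matrix(cohort.matrix, sig)
        result = stage_correlated_pairs(indicator, cohort.stages, 0.05)
        assert result["rho"].abs().mean() < 0.1

    def test_graded_probabilities_raise_severe_scores(self):
        cfg = SimulationConfig(
            n_genes=300, n_planted_pairs=60, n_samples_per_group=50, seed=19
        )
        cohort = simulate_stage_cohort(cfg, (1, 2), (0.2, 0.8), n_stage_pairs=60)
        sig = truth_signature(cohort.truth)
        scores = pd.Series(
            [r.score for r in score_cohort(cohort.matrix, sig)],
            index=cohort.matrix.columns,
        )
        assert scores[cohort.stages == 2].mean() > scores[cohort.stages == 1].mean()


class TestTreatmentStudy:
    def test_determinism(self):
        cfg = TreatmentConfig(n_genes=50, n_de_genes=5, seed=3)
        s1, s2 = simulate_treatment_study(cfg), simulate_treatment_study(cfg)
        pd.testing.assert_frame_equal(s1.control, s2.control)
        pd.testing.assert_frame_equal(s1.treatments["trtA"], s2.treatments["trtA"])
        assert s1.truth_reversed == s2.truth_reversed

    def test_null_effect_type_one_rate(self):
        cfg = TreatmentConfig(n_genes=2000, n_de_genes=100, effect_size=0.0, seed=2)
        study = simulate_treatment_study(cfg)
        stats = two_group_stats(study.model, study.control)
        assert 0.03 <= (stats["p"] < 0.05).mean() <= 0.07

    def test_full_reversal_low_noise_limit(self):
        cfg = TreatmentConfig(
            n_genes=100, n_de_genes=20, effect_size=2.0, noise_sd=0.01,
            reversal_fraction=1.0, seed=6,
        )
        study = simulate_treatment_study(cfg)
        for name, matrix in study.treatments.items():
            stats = two_group_stats(matrix, study.model)
            reversed_p = stats.loc[sorted(study.truth_reversed[name]), "p"]
            assert (reversed_p < 1e-6).all()
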