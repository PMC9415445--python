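"""Seeded synthetic cohorts with the structure the rank-based analysis assumes.

The generators stand in for the study's microarray cohorts and produce:

* case/control cohorts with *planted reversal pairs* — disjoint gene pairs
  whose within-sample ordering is one way in the normal phenotype and
  reversed in the cancer-like phenotype — measured on several "platforms"
  covering overlapping gene subsets;
* per-sample strictly monotone batch distortions (x -> a·x^b + c with
  a, b > 0, c >= 0), which change every value but no within-sample ordering;
* stage cohorts where a subset of pairs shows the cancer ordering with a
  probability that increases with ordinal disease stage;
* a control / disease-model / treatments design with six replicates per
  group, planted differential genes and per-treatment planted reversals.

Intensities are log-normal: baseline gene means are drawn on natural-log
scale and per-sample noise is additive on that scale before exponentiation.
The two genes of a planted pair share a per-sample latent log-intensity
(pair co-expression) and the planted signal is carried by the pair's
log-ratio, distributed N(+log_gap, noise_sd^2) in the normal phenotype and
N(-log_gap, noise_sd^2) in the cancer phenotype.  This mirrors how reversal
pairs behave in real data — two co-regulated genes whose *relative* order
flips — and it keeps the planted truth unambiguous: comparisons that cross
pair boundaries fluctuate with two independent latent intensities and so
are far too unstable to reach a 90% ordering threshold by accident.
Everything is bit-reproducible from (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import SampleAnnotation, validate_expression_matrix
from .reo import A_GT_B, A_LT_B, opposite
from .signature import Signature

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "StageCohort",
    "TreatmentStudy",
    "TreatmentConfig",
    "simulate_case_control",
    "simulate_signature_study",
    "apply_monotone_distortion",
    "simulate_stage_cohort",
    "simulate_treatment_study",
    "truth_signature",
]

_LOG_MEAN = 6.0  # baseline natural-log intensity, exp(6) ~ 400
_LOG_SD = 1.0
_PAIR_LATENT_SD = 2.0  # per-sample latent shared by a planted pair's genes


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the case/control generators.

    Defaults are the conditions of the package's parameter-recovery
    experiment: 1000 genes, 200 planted pairs, 50 samples per phenotype per
    platform, a log-scale separation of 2 between pair members and log-scale
    noise of SD 1, on two discovery platforms plus one filter cohort.
    """

    n_genes: int = 1000
    n_planted_pairs: int = 200
    n_samples_per_group: int = 50
    log_gap: float = 2.0
    noise_sd: float = 1.0
    platforms: tuple[float, ...] = (1.0, 0.9)
    distortion: bool = True
    keep_planted_on_platforms: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_planted_pairs < 1 or self.n_samples_per_group < 1:
            raise ValueError("all counts must be >= 1")
        if 2 * self.n_planted_pairs > self.n_genes:
            raise ValueError("2 * n_planted_pairs must not exceed n_genes")
        if self.log_gap <= 0:
            raise ValueError("log_gap must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not self.platforms or any(not 0 < f <= 1 for f in self.platforms):
            raise ValueError("platform fractions must lie in (0, 1]")


@dataclass
class SyntheticCohort:
    """matrices[platform][phenotype] -> gene x sample DataFrame; ``truth``
    lists the planted pairs with their normal-phenotype ordering."""

    matrices: dict[str, dict[str, pd.DataFrame]]
    annotation: SampleAnnotation
    truth: pd.DataFrame
    config: SimulationConfig


@dataclass
class StageCohort:
    matrix: pd.DataFrame
    stages: pd.Series
    truth: pd.DataFrame
    truth_stage_pairs: pd.DataFrame
    flip_probabilities: dict[int, float]


@dataclass(frozen=True)
class TreatmentConfig:
    """Conditions for the control / model / treatments design.

    Six replicates per group; planted differential genes are shifted on log
    scale by ``effect_size`` in the model group and, for each treatment's
    planted-reversed subset, pulled back toward control by
    ``reversal_fraction`` of that shift.
    """

    n_genes: int = 2000
    n_de_genes: int = 100
    n_replicates: int = 6
    effect_size: float = 1.0
    noise_sd: float = 0.5
    treatments: tuple[str, ...] = ("trtA", "trtB", "trtC", "trtD")
    reversed_fraction_of_de: float = 0.5
    reversal_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_de_genes > self.n_genes:
            raise ValueError("n_de_genes must not exceed n_genes")
        if self.n_replicates < 2:
            raise ValueError("need >=2 replicates per group")
        if not 0 <= self.reversal_fraction <= 1:
            raise ValueError("reversal_fraction must lie in [0, 1]")


@dataclass
class TreatmentStudy:
    control: pd.DataFrame
    model: pd.DataFrame
    treatments: dict[str, pd.DataFrame]
    truth_de_genes: list[str]
    truth_reversed: dict[str, set[str]]
    config: TreatmentConfig


def _gene_ids(n: int) -> np.ndarray:
    width = max(4, len(str(n)))
    return np.array([f"G{i:0{width}d}" for i in range(n)])


@dataclass
class _Layout:
    """Fixed cohort layout drawn once per simulation: gene ids, background
    log-means, and the planted pairs (low/high gene positions, pair base)."""

    genes: np.ndarray
    mu_background: np.ndarray
    low_idx: np.ndarray  # lower member in the normal phenotype
    high_idx: np.ndarray
    pair_base: np.ndarray
    truth: pd.DataFrame

    @property
    def planted_idx(self) -> np.ndarray:
        return np.concatenate([self.low_idx, self.high_idx])


def _planted_layout(config: SimulationConfig, rng: np.random.Generator) -> _Layout:
    genes = _gene_ids(config.n_genes)
    mu = rng.normal(_LOG_MEAN, _LOG_SD, size=config.n_genes)
    chosen = rng.choice(config.n_genes, size=2 * config.n_planted_pairs, replace=False)
    low_idx = chosen[0::2]
    high_idx = chosen[1::2]
    base = rng.normal(_LOG_MEAN, _LOG_SD, size=config.n_planted_pairs)

    rows = []
    for lo, hi in zip(low_idx, high_idx):
        a, b = genes[lo], genes[hi]
        if a < b:
            rows.append((a, b, A_LT_B))  # a below b in normal samples
        else:
            rows.append((b, a, A_GT_B))
    truth = pd.DataFrame(rows, columns=["gene_a", "gene_b", "normal_direction"])
    truth["cancer_direction"] = truth["normal_direction"].map(opposite)
    truth = truth.sort_values(["gene_a", "gene_b"], kind="stable").reset_index(drop=True)
    return _Layout(genes, mu, low_idx, high_idx, base, truth)


def _sample_matrix(
    layout: _Layout,
    phenotype: str,
    n_samples: int,
    config: SimulationConfig,
    rng: np.random.Generator,
    prefix: str,
) -> pd.DataFrame:
    """Draw one group: background genes are i.i.d. log-normal; each planted
    pair gets a shared per-sample latent intensity plus a log-ratio centred
    at +log_gap (normal) or -log_gap (cancer) with SD noise_sd."""
    n_genes = len(layout.genes)
    log_values = layout.mu_background[:, None] + rng.normal(
        0.0, config.noise_sd, size=(n_genes, n_samples)
    )
    n_pairs = len(layout.pair_base)
    latent = layout.pair_base[:, None] + rng.normal(
        0.0, _PAIR_LATENT_SD, size=(n_pairs, n_samples)
    )
    sign = 1.0 if phenotype == "normal" else -1.0
    log_ratio = rng.normal(sign * config.log_gap, config.noise_sd, size=(n_pairs, n_samples))
    log_values[layout.low_idx] = latent - log_ratio / 2.0
    log_values[layout.high_idx] = latent + log_ratio / 2.0
    return pd.DataFrame(
        np.exp(log_values),
        index=pd.Index(layout.genes, name="feature_id"),
        columns=[f"{prefix}_{i:03d}" for i in range(n_samples)],
    )


def simulate_case_control(config: SimulationConfig) -> SyntheticCohort:
    """Two-phenotype cohorts with planted reversal pairs on each platform.

    Baseline gene means are drawn once; each platform then gets its own
    samples of both phenotypes, restricted to its gene subset.  With
    ``distortion`` every sample receives its own strictly monotone transform.
    """
    rng = np.random.default_rng(config.seed)
    layout = _planted_layout(config, rng)

    matrices: dict[str, dict[str, pd.DataFrame]] = {}
    ann_rows = []
    for p, fraction in enumerate(config.platforms):
        platform = f"platform{p + 1}"
        subset = _platform_subset(config, layout, fraction, rng)
        matrices[platform] = {}
        for phenotype in ("normal", "cancer"):
            matrix = _sample_matrix(
                layout,
                phenotype,
                config.n_samples_per_group,
                config,
                rng,
                prefix=f"{platform}_{phenotype}",
            ).iloc[subset]
            if config.distortion:
                matrix = apply_monotone_distortion(
                    matrix, seed=int(rng.integers(0, 2**31 - 1))
                )
            matrices[platform][phenotype] = matrix
            ann_rows.extend(
                (sid, phenotype, "", platform) for sid in matrix.columns
            )
    annotation = SampleAnnotation(
        pd.DataFrame(ann_rows, columns=["sample_id", "phenotype", "stage", "dataset_id"])
    )
    return SyntheticCohort(matrices, annotation, layout.truth, config)


def _platform_subset(
    config: SimulationConfig,
    layout: _Layout,
    fraction: float,
    rng: np.random.Generator,
) -> np.ndarray:
    if fraction >= 1.0:
        return np.arange(config.n_genes)
    subset = rng.choice(
        config.n_genes, size=max(1, int(round(fraction * config.n_genes))), replace=False
    )
    if config.keep_planted_on_platforms:
        subset = np.union1d(subset, layout.planted_idx)
    return np.sort(subset)


def simulate_signature_study(config: SimulationConfig):
    """The full discovery layout: the configured discovery platforms plus an
    independent normal-only filter cohort and a held-out case/control test
    cohort, all on the same planted truth.

    Returns (platform_cohorts, filter_matrix, test_cohort, truth) where
    ``platform_cohorts`` feeds ``signature.build_signature`` directly and
    ``test_cohort`` is {"normal": matrix, "cancer": matrix}.
    """
    rng = np.random.default_rng(config.seed)
    layout = _planted_layout(config, rng)

    def draw_group(phenotype: str, prefix: str) -> pd.DataFrame:
        matrix = _sample_matrix(
            layout, phenotype, config.n_samples_per_group, config, rng, prefix
        )
        if config.distortion:
            matrix = apply_monotone_distortion(matrix, seed=int(rng.integers(0, 2**31 - 1)))
        return matrix

    platform_cohorts: dict[str, dict[str, pd.DataFrame]] = {}
    for p, fraction in enumerate(config.platforms):
        platform = f"platform{p + 1}"
        subset = _platform_subset(config, layout, fraction, rng)
        platform_cohorts[platform] = {
            phenotype: draw_group(phenotype, f"{platform}_{phenotype}").iloc[subset]
            for phenotype in ("normal", "cancer")
        }
    filter_matrix = draw_group("normal", "filter_normal")
    test_cohort = {
        "normal": draw_group("normal", "test_normal"),
        "cancer": draw_group("cancer", "test_cancer"),
    }
    return platform_cohorts, filter_matrix, test_cohort, layout.truth


def apply_monotone_distortion(matrix: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Give each sample its own strictly increasing transform x -> a·x^b + c.

    a is log-uniform in [0.5, 2], b log-uniform in [0.7, 1.4], c uniform in
    [0, median of the column]; all strictly increasing on positive values, so
    every within-sample ordering is exactly preserved.
    """
    values = matrix.to_numpy(dtype=float)
    if (values <= 0).any():
        raise ValueError("monotone distortion requires strictly positive values")
    rng = np.random.default_rng(seed)
    n_samples = values.shape[1]
    a = np.exp(rng.uniform(np.log(0.5), np.log(2.0), size=n_samples))
    b = np.exp(rng.uniform(np.log(0.7), np.log(1.4), size=n_samples))
    c = rng.uniform(0.0, 1.0, size=n_samples) * np.median(values, axis=0)
    distorted = a[None, :] * values ** b[None, :] + c[None, :]
    out = pd.DataFrame(distorted, index=matrix.index, columns=matrix.columns)
    return validate_expression_matrix(out)


def simulate_stage_cohort(
    config: SimulationConfig,
    stage_levels: tuple[int, ...] = (1, 2),
    flip_probabilities: tuple[float, ...] = (0.2, 0.8),
    n_samples_per_stage: int | None = None,
    n_stage_pairs: int | None = None,
    sample_seed: int | None = None,
) -> StageCohort:
    """One cohort whose planted pairs show the cancer-like ordering with a
    stage-dependent probability.

    ``flip_probabilities`` must be nondecreasing in stage.  For the
    ``n_stage_pairs`` stage-related pairs (default: half the planted pairs)
    each sample independently shows the cancer ordering with its stage's
    probability; the remaining planted pairs use the lowest-stage probability
    throughout.  Pair-member values are drawn so the Bernoulli outcome fixes
    the ordering exactly.

    The planted layout and the stage-pair selection depend only on
    ``config.seed``; ``sample_seed`` (default: derived from ``config.seed``)
    draws the samples, so distinct sample seeds emulate independent cohorts
    measuring the same biology.
    """
    if len(stage_levels) != len(flip_probabilities):
        raise ValueError("one flip probability per stage level")
    if any(
        flip_probabilities[i + 1] < flip_probabilities[i]
        for i in range(len(flip_probabilities) - 1)
    ):
        raise ValueError("flip probabilities must be nondecreasing in stage")
    if n_samples_per_stage is None:
        n_samples_per_stage = config.n_samples_per_group
    if n_stage_pairs is None:
        n_stage_pairs = config.n_planted_pairs // 2
    if n_stage_pairs > config.n_planted_pairs:
        raise ValueError("n_stage_pairs must not exceed n_planted_pairs")

    layout_rng = np.random.default_rng(config.seed)
    layout = _planted_layout(config, layout_rng)
    genes, truth = layout.genes, layout.truth
    stage_pair_rows = layout_rng.choice(len(truth), size=n_stage_pairs, replace=False)
    is_stage_pair = np.zeros(len(truth), dtype=bool)
    is_stage_pair[stage_pair_rows] = True

    if sample_seed is None:
        sample_seed = int(layout_rng.integers(0, 2**31 - 1))
    rng = np.random.default_rng(sample_seed)
    stage_of_sample = np.repeat(stage_levels, n_samples_per_stage)
    prob_of_stage = dict(zip(stage_levels, flip_probabilities))
    n_total = len(stage_of_sample)
    sample_ids = [f"stage{s}_{i:03d}" for i, s in enumerate(stage_of_sample)]

    log_values = layout.mu_background[:, None] + rng.normal(
        0.0, config.noise_sd, size=(config.n_genes, n_total)
    )

    gene_pos = {g: i for i, g in enumerate(genes)}
    base_p = flip_probabilities[0]
    gap = config.log_gap
    for row_i, row in truth.iterrows():
        ia, ib = gene_pos[row["gene_a"]], gene_pos[row["gene_b"]]
        probs = (
            np.array([prob_of_stage[s] for s in stage_of_sample])
            if is_stage_pair[row_i]
            else np.full(n_total, base_p)
        )
        cancer_like = rng.random(n_total) < probs
        base = rng.normal(_LOG_MEAN, _LOG_SD)
        jitter = rng.uniform(-gap / 4.0, gap / 4.0, size=(2, n_total))
        lo = base - gap / 2.0 + jitter[0]
        hi = base + gap / 2.0 + jitter[1]
        a_high = cancer_like if row["cancer_direction"] == A_GT_B else ~cancer_like
        log_values[ia] = np.where(a_high, hi, lo)
        log_values[ib] = np.where(a_high, lo, hi)

    matrix = pd.DataFrame(
        np.exp(log_values),
        index=pd.Index(genes, name="feature_id"),
        columns=sample_ids,
    )
    if config.distortion:
        matrix = apply_monotone_distortion(matrix, seed=int(rng.integers(0, 2**31 - 1)))
    stages = pd.Series(stage_of_sample, index=sample_ids, name="stage")
    return StageCohort(
        matrix=matrix,
        stages=stages,
        truth=truth,
        truth_stage_pairs=truth.iloc[np.sort(stage_pair_rows)].reset_index(drop=True),
        flip_probabilities=prob_of_stage,
    )


def simulate_treatment_study(config: TreatmentConfig) -> TreatmentStudy:
    """Control / disease-model / treatment groups with planted effects.

    Differential genes get a random-signed log-scale shift of ``effect_size``
    in the model group; each treatment pulls its planted-reversed subset back
    toward control by ``reversal_fraction`` of the shift.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    mu = rng.normal(_LOG_MEAN, _LOG_SD, size=config.n_genes)
    de_idx = rng.choice(config.n_genes, size=config.n_de_genes, replace=False)
    signs = rng.choice([-1.0, 1.0], size=config.n_de_genes)
    shift = np.zeros(config.n_genes)
    shift[de_idx] = signs * config.effect_size

    def draw(mu_group: np.ndarray, prefix: str) -> pd.DataFrame:
        log_values = mu_group[:, None] + rng.normal(
            0.0, config.noise_sd, size=(config.n_genes, config.n_replicates)
        )
        return pd.DataFrame(
            np.exp(log_values),
            index=pd.Index(genes, name="feature_id"),
            columns=[f"{prefix}_{i}" for i in range(config.n_replicates)],
        )

    control = draw(mu, "control")
    model = draw(mu + shift, "model")

    treatments: dict[str, pd.DataFrame] = {}
    truth_reversed: dict[str, set[str]] = {}
    n_rev = int(round(config.reversed_fraction_of_de * config.n_de_genes))
    for name in config.treatments:
        rev_idx = rng.choice(de_idx, size=n_rev, replace=False)
        mu_trt = mu + shift
        mu_trt[rev_idx] -= config.reversal_fraction * shift[rev_idx]
        treatments[name] = draw(mu_trt, name)
        truth_reversed[name] = set(genes[np.sort(rev_idx)])

    return TreatmentStudy(
        control=control,
        model=model,
        treatments=treatments,
        truth_de_genes=list(genes[np.sort(de_idx)]),
        truth_reversed=truth_reversed,
        config=config,
    )


def truth_signature(truth: pd.DataFrame) -> Signature:
    """Wrap a planted-truth table as a Signature for scoring experiments."""
    pairs = truth[["gene_a", "gene_b", "normal_direction", "cancer_direction"]].copy()
    return Signature(pairs.reset_index(drop=True), build_config={"source": "planted_truth"})
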