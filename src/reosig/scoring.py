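"""Per-sample incidence-risk scoring against a reversal-pair signature.

For one sample, let m be the number of signature pairs that are evaluable
(both genes measured and not exactly tied) and n the number of those showing
the cancer-characteristic ordering; the incidence-risk score is n/m.  Since
the score depends only on within-sample orderings it is invariant to any
strictly increasing per-sample transform of the expression values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .signature import Signature

CANCER_LIKE = "cancer_like"
NORMAL_LIKE = "normal_like"

__all__ = [
    "ScoreResult",
    "CohortComparison",
    "risk_score",
    "score_cohort",
    "classify",
    "roc_auc",
    "compare_score_groups",
    "CANCER_LIKE",
    "NORMAL_LIKE",
]


@dataclass
class ScoreResult:
    sample_id: str
    m: int
    n: int
    score: float
    coverage: float

    def __post_init__(self) -> None:
        if not 0 <= self.n <= self.m:
            raise ValueError("need 0 <= n <= m")


@dataclass
class CohortComparison:
    label_a: str
    label_b: str
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    statistic: float
    p_value: float
    method: str


def _evaluate_sample(
    values: pd.Series, sig: Signature
) -> tuple[int, int]:
    pairs = sig.pairs
    present = pairs["gene_a"].isin(values.index) & pairs["gene_b"].isin(values.index)
    sub = pairs[present]
    if sub.empty:
        return 0, 0
    a = values.loc[sub["gene_a"]].to_numpy()
    b = values.loc[sub["gene_b"]].to_numpy()
    tied = a == b
    a_gt_b = a > b
    wants_gt = (sub["cancer_direction"] == "a_gt_b").to_numpy()
    cancer_like = np.where(wants_gt, a_gt_b, ~a_gt_b) & ~tied
    m = int((~tied).sum())
    n = int(cancer_like.sum())
    return m, n


def risk_score(
    sample: pd.Series | pd.DataFrame,
    sig: Signature,
    *,
    coverage_floor: float = 0.5,
) -> ScoreResult:
    """Score one sample: n/m over evaluable signature pairs.

    ``sample`` is a Series indexed by gene id (or a one-column DataFrame).
    Pairs with a missing gene or an exact tie are excluded from both n and m;
    ``coverage`` records the evaluable fraction of the full signature so
    scores from platforms with partial gene coverage stay comparable.
    """
    if isinstance(sample, pd.DataFrame):
        if sample.shape[1] != 1:
            raise ValueError("risk_score expects a single sample")
        sample_id = str(sample.columns[0])
        sample = sample.iloc[:, 0]
    else:
        sample_id = str(sample.name) if sample.name is not None else "sample"
    if not len(sig):
        raise ValueError("empty signature")
    m, n = _evaluate_sample(sample, sig)
    coverage = m / len(sig)
    if m == 0 or coverage < coverage_floor:
        n_missing = len(sig) - m
        raise ValueError(
            f"sample {sample_id!r}: only {m}/{len(sig)} signature pairs evaluable "
            f"({n_missing} missing or tied), below coverage floor {coverage_floor}"
        )
    return ScoreResult(sample_id, m, n, n / m, coverage)


def score_cohort(
    matrix: pd.DataFrame,
    sig: Signature,
    *,
    coverage_floor: float = 0.5,
) -> list[ScoreResult]:
    """Score every sample of a cohort, preserving sample order."""
    return [
        risk_score(matrix[col].rename(col), sig, coverage_floor=coverage_floor)
        for col in matrix.columns
    ]


def scores_frame(results: list[ScoreResult], cutoff: float = 0.5) -> pd.DataFrame:
    """Tabulate score results, adding the majority-vote label."""
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in results],
            "m": [r.m for r in results],
            "n": [r.n for r in results],
            "score": [r.score for r in results],
            "coverage": [r.coverage for r in results],
            "label": [classify(r.score, cutoff) for r in results],
        }
    )


def classify(score: float, cutoff: float = 0.5) -> str:
    """Majority vote: cancer_like iff more than ``cutoff`` of pairs flipped.

    An exact tie (score == cutoff) is called normal_like.
    """
    if not 0.0 <= score <= 1.0:
        raise ValueError("score must lie in [0, 1]")
    return CANCER_LIKE if score > cutoff else NORMAL_LIKE


def roc_auc(
    scores: np.ndarray | list[float],
    labels: np.ndarray | list[int],
    n_boot: int = 2000,
    seed: int | None = None,
) -> tuple[float, float, float]:
    """AUC by the rank (Mann-Whitney) construction, ties counted 1/2, with a
    seeded percentile-bootstrap confidence interval over samples.

    ``labels`` are 1 for the positive (cancer) class, 0 otherwise.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be 0/1")
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")

    def _auc(s: np.ndarray, y: np.ndarray) -> float:
        ranks = stats.rankdata(s)
        pos_rank_sum = ranks[y == 1].sum()
        npos = int(y.sum())
        nneg = len(y) - npos
        u = pos_rank_sum - npos * (npos + 1) / 2.0
        return float(u / (npos * nneg))

    point = _auc(scores, labels)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    idx = np.arange(len(scores))
    for b in range(n_boot):
        take = rng.choice(idx, size=len(idx), replace=True)
        y = labels[take]
        if y.sum() == 0 or y.sum() == len(y):
            boots[b] = np.nan
            continue
        boots[b] = _auc(scores[take], y)
    boots = boots[~np.isnan(boots)]
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return point, float(lo), float(hi)


def compare_score_groups(
    scores_a: np.ndarray | list[float],
    scores_b: np.ndarray | list[float],
    *,
    label_a: str = "group_a",
    label_b: str = "group_b",
    exact_max_n: int = 20,
) -> CohortComparison:
    """Two-sided Wilcoxon rank-sum comparison of two score distributions.

    Uses the exact null when the combined sample size is at most
    ``exact_max_n`` and there are no cross-group ties, otherwise the normal
    approximation with tie correction.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < pooled.size
    if a.size + b.size <= exact_max_n and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return CohortComparison(
        label_a=label_a,
        label_b=label_b,
        n_a=int(a.size),
        n_b=int(b.size),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method=method,
    )
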