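"""Stage correlation of signature pairs and hypergeometric enrichment.

Two questions are answered here.  First, which signature pairs track disease
severity: each pair's per-sample binary indicator (1 when the sample shows
the cancer-characteristic ordering) is correlated with the ordinal stage by
Spearman's rank correlation, with Benjamini-Hochberg control across pairs.
Second, whether gene or pair lists overlap more than chance and whether a
gene list is enriched in annotated pathways, both via the upper-tail
hypergeometric probability

    P(X >= k) = 1 - sum_{i<k} C(m,i) C(N-m, n-i) / C(N,n)

evaluated in log-space for numerical safety.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .signature import Signature

logger = logging.getLogger(__name__)

__all__ = [
    "PairStageResult",
    "reo_indicator_matrix",
    "stage_correlated_pairs",
    "hypergeometric_tail",
    "overlap_significance",
    "pathway_enrichment",
    "combine_pair_lists",
]

# beyond this many distinct stage-label arrangements the exact permutation
# null is abandoned for the t approximation even at small n
_MAX_EXACT_PERMS = 100_000


@dataclass
class PairStageResult:
    gene_a: str
    gene_b: str
    rho: float
    p_value: float
    q_value: float


def reo_indicator_matrix(matrix: pd.DataFrame, sig: Signature) -> pd.DataFrame:
    """Binary pair x sample grid: 1 where the pair shows its cancer ordering.

    Rows are indexed by (gene_a, gene_b).  Ties are NaN; pairs with a gene
    unmeasured in the cohort appear as all-NaN rows (count logged).
    """
    pairs = sig.pairs
    index = pd.MultiIndex.from_arrays(
        [pairs["gene_a"], pairs["gene_b"]], names=["gene_a", "gene_b"]
    )
    out = pd.DataFrame(np.nan, index=index, columns=matrix.columns)
    present = pairs["gene_a"].isin(matrix.index) & pairs["gene_b"].isin(matrix.index)
    n_missing = int((~present).sum())
    if n_missing:
        logger.info("reo_indicator_matrix: %d pairs with unmeasured genes", n_missing)
    sub = pairs[present]
    if sub.empty:
        return out
    a = matrix.loc[sub["gene_a"]].to_numpy()
    b = matrix.loc[sub["gene_b"]].to_numpy()
    wants_gt = (sub["cancer_direction"] == "a_gt_b").to_numpy()[:, None]
    ind = np.where(wants_gt, a > b, a < b).astype(float)
    ind[a == b] = np.nan
    out.loc[pd.MultiIndex.from_arrays([sub["gene_a"], sub["gene_b"]])] = ind
    return out


def _multiset_permutation_matrix(values: np.ndarray) -> np.ndarray:
    """All distinct permutations of ``values`` as a (K, n) array.

    Distinct arrangements of a multiset are equiprobable under uniform random
    permutation, so an exact permutation null may enumerate them directly.
    """
    rows = sorted(set(itertools.permutations(values.tolist())))
    return np.asarray(rows, dtype=float)


def _n_distinct_perms(values: np.ndarray) -> float:
    _, counts = np.unique(values, return_counts=True)
    log_count = gammaln(len(values) + 1) - gammaln(counts + 1).sum()
    return float(np.exp(log_count))


def _exact_spearman_pvalue(x: np.ndarray, stage_ranks: np.ndarray, rho_obs: float,
                           perm_cache: dict) -> float:
    key = tuple(stage_ranks.tolist())
    if key not in perm_cache:
        perms = _multiset_permutation_matrix(stage_ranks)
        perm_cache[key] = perms - perms.mean(axis=1, keepdims=True)
    centered_perms = perm_cache[key]
    rx = stats.rankdata(x)
    rx = rx - rx.mean()
    denom = np.linalg.norm(rx) * np.linalg.norm(centered_perms[0])
    if denom == 0:
        return 1.0
    rhos = centered_perms @ rx / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def stage_correlated_pairs(
    indicator: pd.DataFrame,
    stages: pd.Series,
    fdr: float = 0.05,
    *,
    exact_max_n: int = 12,
) -> pd.DataFrame:
    """Spearman correlation of each pair's cancer-ordering indicator with stage.

    ``stages`` maps sample id to an ordinal stage code (e.g. moderate=1 <
    severe=2).  Pairs whose indicator is constant (or all-missing) over the
    usable samples are excluded and logged.  Two-sided p-values use an exact
    permutation null when the usable sample count is below ``exact_max_n``
    (and the number of distinct label arrangements is tractable), otherwise
    the asymptotic t approximation.  Returns a DataFrame with columns
    gene_a, gene_b, rho, p_value, q_value, significant, sorted by p.
    """
    stages = stages.reindex(indicator.columns)
    if stages.isna().any():
        missing = indicator.columns[stages.isna()][0]
        raise ValueError(f"sample {missing!r} has no stage label")
    stage_vals = stages.to_numpy(dtype=float)
    if len(np.unique(stage_vals)) < 2:
        raise ValueError("need at least two distinct stage levels")

    rows = []
    n_excluded = 0
    perm_cache: dict = {}
    for (gene_a, gene_b), row in indicator.iterrows():
        x = row.to_numpy(dtype=float)
        usable = ~np.isnan(x)
        if usable.sum() < 3:
            n_excluded += 1
            continue
        xu = x[usable]
        su = stage_vals[usable]
        if np.all(xu == xu[0]) or len(np.unique(su)) < 2:
            n_excluded += 1
            continue
        rho = float(stats.spearmanr(xu, su).statistic)
        n = len(xu)
        if n < exact_max_n and _n_distinct_perms(su) <= _MAX_EXACT_PERMS:
            p = _exact_spearman_pvalue(xu, stats.rankdata(su), rho, perm_cache)
        else:
            if abs(rho) >= 1.0:
                p = np.finfo(float).tiny
            else:
                t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
                p = 2.0 * stats.t.sf(abs(t), n - 2)
        rows.append((gene_a, gene_b, rho, min(max(p, np.finfo(float).tiny), 1.0)))
    if n_excluded:
        logger.info("stage_correlated_pairs: excluded %d constant/unusable pairs", n_excluded)
    result = pd.DataFrame(rows, columns=["gene_a", "gene_b", "rho", "p_value"])
    if result.empty:
        result["q_value"] = []
        result["significant"] = []
        return result
    reject, qvals, _, _ = multipletests(result["p_value"], alpha=fdr, method="fdr_bh")
    result["q_value"] = qvals
    result["significant"] = reject
    return result.sort_values("p_value", kind="stable").reset_index(drop=True)


def _log_binom(n: float, k: np.ndarray | float) -> np.ndarray | float:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeometric_tail(N: int, m: int, n: int, k: int) -> float:
    """Upper-tail P(X >= k): k or more of n drawn genes fall in a marked set
    of m, drawing without replacement from a universe of N.

    Computed as a log-space sum over the upper tail, which is algebraically
    identical to one minus the lower-sum form of the same distribution.
    """
    if min(N, m, n, k) < 0 or m > N or n > N:
        raise ValueError(f"impossible arguments N={N} m={m} n={n}")
    if k > min(m, n):
        raise ValueError(f"k={k} exceeds min(m, n)={min(m, n)}")
    if k <= max(0, n + m - N):
        return 1.0
    i = np.arange(k, min(m, n) + 1, dtype=float)
    log_terms = _log_binom(m, i) + _log_binom(N - m, n - i) - _log_binom(N, n)
    return float(min(np.exp(logsumexp(log_terms)), 1.0))


def overlap_significance(
    list_a: list | set,
    list_b: list | set,
    universe_size: int,
) -> tuple[int, float]:
    """Hypergeometric tail probability of the observed overlap of two lists
    drawn from a shared universe.  Returns (overlap size, p)."""
    set_a, set_b = set(list_a), set(list_b)
    if len(set_a) > universe_size or len(set_b) > universe_size:
        raise ValueError("list larger than stated universe")
    k = len(set_a & set_b)
    return k, hypergeometric_tail(universe_size, len(set_a), len(set_b), k)


def pathway_enrichment(
    genes: list[str],
    gene_sets: dict[str, set[str]],
    N: int,
    fdr: float = 0.05,
    *,
    uncorrected: bool = False,
) -> pd.DataFrame:
    """Hypergeometric enrichment of ``genes`` in each annotated set.

    ``N`` is the explicit universe size (genes detected on the platform) and
    is never inferred from the GMT.  Sets with zero overlap are omitted.
    With ``uncorrected`` the significance flag uses raw p < fdr instead of
    the BH q-value — useful when too few genes of interest leave the FDR
    criterion powerless.
    """
    interested = sorted(set(genes))
    if not interested:
        raise ValueError("empty gene list")
    n = len(interested)
    if N < n:
        raise ValueError(f"universe N={N} smaller than interested gene count {n}")
    rows = []
    for name, members in gene_sets.items():
        m = len(members)
        k = len(members & set(interested))
        if k == 0:
            continue
        rows.append((name, N, m, n, k, hypergeometric_tail(N, m, n, k)))
    result = pd.DataFrame(rows, columns=["set_name", "N", "m", "n", "k", "p_value"])
    if result.empty:
        result["q_value"] = []
        result["significant"] = []
        return result
    _, qvals, _, _ = multipletests(result["p_value"], alpha=fdr, method="fdr_bh")
    result["q_value"] = qvals
    if uncorrected:
        result["significant"] = result["p_value"] < fdr
    else:
        result["significant"] = result["q_value"] < fdr
    return result.sort_values("p_value", kind="stable").reset_index(drop=True)


def combine_pair_lists(
    list_a: list[tuple[str, str]],
    list_b: list[tuple[str, str]],
) -> list[tuple[str, str]]:
    """Deduplicated union of two canonical pair lists, first-seen order."""
    seen: dict[tuple[str, str], None] = {}
    for pair in itertools.chain(list_a, list_b):
        seen.setdefault(tuple(pair), None)
    return list(seen)
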