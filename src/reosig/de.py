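"""Two-group differential expression and treatment-reversal frequency.

The design emulated here: a disease model group versus control (six
replicates each), plus several treatment groups measured on the same genes.
Per gene, fold-change is the ratio of arithmetic group means on the loaded
intensity scale and significance is the pooled-variance two-sample Student
t-test (df = n_a + n_b - 2).  A model-vs-control significant gene is counted
as *reversed* under a treatment when its treatment-vs-model p-value falls
below a threshold; counting is by p-value alone by default, with an optional
mode that additionally requires the treatment effect to oppose the disease
effect.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "two_group_stats",
    "student_t_pvalue",
    "map_orthologs",
    "treatment_reversal_table",
]

DEFAULT_THRESHOLDS = (0.05, 0.1, 0.2)


def student_t_pvalue(t: float, df: int) -> float:
    """Two-sided tail probability of the central t distribution."""
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(2.0 * stats.t.sf(abs(t), df))


def two_group_stats(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    *,
    welch: bool = False,
    log2_fc: bool = False,
) -> pd.DataFrame:
    """Per-gene fold-change and Student t statistics, group_a vs group_b.

    fc = mean(a)/mean(b) on the loaded scale (or its log2 with ``log2_fc``);
    t uses the pooled-variance formula unless ``welch``.  Genes with zero
    pooled variance get p = NaN (degenerate, logged) rather than a silent 0.
    Returns columns gene, fc, t, p indexed like group_a.
    """
    if set(group_a.index) != set(group_b.index):
        raise ValueError("groups must cover identical gene sets")
    group_b = group_b.loc[group_a.index]
    n_a, n_b = group_a.shape[1], group_b.shape[1]
    if n_a < 2 or n_b < 2:
        raise ValueError("need >=2 samples per group")
    a = group_a.to_numpy(dtype=float)
    b = group_b.to_numpy(dtype=float)
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    var_a = a.var(axis=1, ddof=1)
    var_b = b.var(axis=1, ddof=1)
    if welch:
        se2 = var_a / n_a + var_b / n_b
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (mean_a - mean_b) / np.sqrt(se2)
            df = se2**2 / ((var_a / n_a) ** 2 / (n_a - 1) + (var_b / n_b) ** 2 / (n_b - 1))
    else:
        pooled = ((n_a - 1) * var_a + (n_b - 1) * var_b) / (n_a + n_b - 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (mean_a - mean_b) / np.sqrt(pooled * (1.0 / n_a + 1.0 / n_b))
        df = np.full_like(t, float(n_a + n_b - 2))
    degenerate = ~np.isfinite(t)
    zero_diff = degenerate & (mean_a == mean_b)
    t = np.where(zero_diff, 0.0, t)
    degenerate &= ~zero_diff
    if degenerate.any():
        logger.warning("two_group_stats: %d genes with zero pooled variance", degenerate.sum())
    p = np.where(
        degenerate, np.nan, 2.0 * stats.t.sf(np.abs(np.where(degenerate, 0.0, t)), df)
    )
    p = np.where(zero_diff, 1.0, p)
    fc = mean_a / mean_b
    if log2_fc:
        fc = np.log2(fc)
    return pd.DataFrame({"gene": group_a.index, "fc": fc, "t": t, "p": p}).set_index(
        "gene", drop=False
    )


def map_orthologs(
    genes: list[str],
    ortholog_map: dict[str, list[str]],
) -> tuple[list[str], int]:
    """Translate gene identifiers through strict 1:1 ortholog assignments.

    Genes mapping to zero or to multiple targets are dropped; the second
    return value counts them.  Output is deduplicated, input order kept.
    """
    mapped: dict[str, None] = {}
    n_unmapped = 0
    for gene in genes:
        targets = ortholog_map.get(gene, [])
        if len(targets) != 1:
            n_unmapped += 1
            continue
        mapped.setdefault(targets[0], None)
    if n_unmapped:
        logger.info("map_orthologs: %d genes unmapped or ambiguous", n_unmapped)
    return list(mapped), n_unmapped


def treatment_reversal_table(
    model_vs_control: pd.DataFrame,
    treatment_stats: dict[str, pd.DataFrame],
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    *,
    alpha: float = 0.05,
    require_direction: bool = False,
) -> pd.DataFrame:
    """Per-gene treatment-reversal frequency table.

    ``model_vs_control`` is a two_group_stats result; genes with p < ``alpha``
    are retained (uncorrected, matching the small-panel design).  For each
    retained gene every treatment-vs-model p-value is recorded and the number
    of treatments with p strictly below each threshold is counted.  With
    ``require_direction`` a treatment only counts when its t statistic
    opposes the sign of the disease effect.
    """
    thresholds = tuple(sorted(thresholds))
    sig = model_vs_control[model_vs_control["p"] < alpha].copy()
    sig = sig.sort_values("p", kind="stable")
    for name, table in treatment_stats.items():
        missing = set(sig.index) - set(table.index)
        if missing:
            raise ValueError(
                f"treatment {name!r} missing {len(missing)} filtered genes, "
                f"first: {sorted(missing)[0]!r}"
            )
    out = sig[["gene", "fc", "t", "p"]].copy()
    treatment_names = list(treatment_stats)
    for name in treatment_names:
        out[f"p_{name}"] = treatment_stats[name].loc[sig.index, "p"]
        if require_direction:
            opposing = (
                np.sign(treatment_stats[name].loc[sig.index, "t"]) != np.sign(sig["t"])
            )
            out[f"_counts_{name}"] = np.where(opposing, out[f"p_{name}"], np.inf)
        else:
            out[f"_counts_{name}"] = out[f"p_{name}"]
    count_cols = [f"_counts_{n}" for n in treatment_names]
    for thr in thresholds:
        out[f"num_p_lt_{thr:g}"] = (out[count_cols] < thr).sum(axis=1)
    out = out.drop(columns=count_cols)
    return out
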