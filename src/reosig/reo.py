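"""Within-sample relative expression orderings (REOs) and stable gene pairs.

For two genes A and B measured in one sample, the REO is simply whether
A > B or A < B in that sample.  Because any batch effect that acts as a
strictly increasing per-sample transform preserves every within-sample
ordering, statistics built purely from REOs are batch-invariant.

A gene pair is *stable* in a phenotype when one direction holds in at least
(or, in strict mode, more than) a threshold fraction of that phenotype's
samples — 90% in the default configuration.  A pair stable in both
phenotypes but with opposite directions is a *reversal pair*, the building
block of the qualitative signature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

A_GT_B = "a_gt_b"
A_LT_B = "a_lt_b"

__all__ = [
    "A_GT_B",
    "A_LT_B",
    "StablePairSet",
    "ReversalPairSet",
    "canonical_pair",
    "pair_support",
    "stable_pairs",
    "reversal_pairs",
]


def canonical_pair(gene_a: str, gene_b: str, direction: str) -> tuple[str, str, str]:
    """Orient a pair so gene_a sorts lexicographically before gene_b.

    The direction flips when the genes are swapped, so the biology encoded
    (which gene is higher) is unchanged.
    """
    if gene_a == gene_b:
        raise ValueError(f"pair must use two distinct genes, got {gene_a!r} twice")
    if direction not in (A_GT_B, A_LT_B):
        raise ValueError(f"unknown direction {direction!r}")
    if gene_a < gene_b:
        return gene_a, gene_b, direction
    flipped = A_LT_B if direction == A_GT_B else A_GT_B
    return gene_b, gene_a, flipped


def opposite(direction: str) -> str:
    return A_LT_B if direction == A_GT_B else A_GT_B


@dataclass
class StablePairSet:
    """Canonical gene pairs with one REO direction supported in >= (or >)
    ``threshold`` of ``n_samples`` samples of one phenotype.

    ``pairs`` columns: gene_a, gene_b, direction, support_fraction.
    """

    pairs: pd.DataFrame
    threshold: float
    n_samples: int
    phenotype_label: str
    inclusive: bool = True

    def __post_init__(self) -> None:
        if not 0.5 < self.threshold <= 1.0:
            raise ValueError("threshold must lie in (0.5, 1]")
        key = self.pairs[["gene_a", "gene_b"]]
        if key.duplicated().any():
            raise ValueError("duplicate canonical pair in StablePairSet")
        if len(self.pairs):
            ok = (
                self.pairs["support_fraction"] >= self.threshold
                if self.inclusive
                else self.pairs["support_fraction"] > self.threshold
            )
            if not ok.all():
                raise ValueError("pair below stability threshold in StablePairSet")

    def __len__(self) -> int:
        return len(self.pairs)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            handle.write(
                f"# stable pairs: threshold={self.threshold} inclusive={self.inclusive} "
                f"n_samples={self.n_samples} phenotype={self.phenotype_label}\n"
            )
            self.pairs.to_csv(handle, sep="\t", index=False)


@dataclass
class ReversalPairSet:
    """Pairs stable in two groups with opposite directions.

    ``pairs`` columns: gene_a, gene_b, direction_group1, direction_group2,
    support_group1, support_group2.
    """

    pairs: pd.DataFrame
    group1_label: str
    group2_label: str

    def __post_init__(self) -> None:
        if len(self.pairs):
            same = self.pairs["direction_group1"] == self.pairs["direction_group2"]
            if same.any():
                raise ValueError("reversal pair with identical directions in both groups")

    def __len__(self) -> int:
        return len(self.pairs)

    def pair_keys(self) -> set[tuple[str, str]]:
        return set(zip(self.pairs["gene_a"], self.pairs["gene_b"]))

    def swapped(self) -> "ReversalPairSet":
        out = self.pairs.rename(
            columns={
                "direction_group1": "direction_group2",
                "direction_group2": "direction_group1",
                "support_group1": "support_group2",
                "support_group2": "support_group1",
            }
        )[self.pairs.columns]
        return ReversalPairSet(out, self.group2_label, self.group1_label)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            handle.write(
                f"# reversal pairs: group1={self.group1_label} group2={self.group2_label}\n"
            )
            self.pairs.to_csv(handle, sep="\t", index=False)


def pair_support(matrix: pd.DataFrame, gene_a: str, gene_b: str) -> tuple[float, float, float]:
    """Fractions of samples with a>b, a<b, and a==b; they sum to 1."""
    for gene in (gene_a, gene_b):
        if gene not in matrix.index:
            raise KeyError(f"gene {gene!r} not in matrix")
    a = matrix.loc[gene_a].to_numpy()
    b = matrix.loc[gene_b].to_numpy()
    n = a.size
    gt = float(np.sum(a > b)) / n
    lt = float(np.sum(a < b)) / n
    return gt, lt, 1.0 - gt - lt


def stable_pairs(
    matrix: pd.DataFrame,
    threshold: float = 0.9,
    *,
    inclusive: bool = True,
    phenotype_label: str = "",
    block_size: int = 256,
) -> StablePairSet:
    """All canonical gene pairs whose majority REO direction meets ``threshold``.

    The pair space is swept in row blocks so at most ``block_size`` x G x S
    comparisons are materialised at a time; the result is bit-identical to
    the naive per-pair counting loop.  Ties count toward neither direction
    but stay in the denominator, so heavily tied pairs simply fail the
    threshold.
    """
    if not 0.5 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0.5, 1]: directions are not exclusive below")
    if matrix.shape[0] < 2 or matrix.shape[1] < 1:
        raise ValueError("need at least 2 genes and 1 sample")
    ordered = matrix.sort_index(kind="stable")
    genes = ordered.index.to_numpy()
    values = ordered.to_numpy()
    n_genes, n_samples = values.shape
    need = (
        int(np.ceil(threshold * n_samples))
        if inclusive
        else int(np.floor(threshold * n_samples)) + 1
    )

    rows_a, rows_b, directions, supports = [], [], [], []
    for start in range(0, n_genes, block_size):
        stop = min(start + block_size, n_genes)
        block = values[start:stop]  # (B, S)
        # counts of block-gene > other-gene across samples: (B, G)
        gt_counts = (block[:, None, :] > values[None, :, :]).sum(axis=2)
        lt_counts = (block[:, None, :] < values[None, :, :]).sum(axis=2)
        for bi in range(stop - start):
            i = start + bi
            gt_row = gt_counts[bi, i + 1 :]
            lt_row = lt_counts[bi, i + 1 :]
            best = np.maximum(gt_row, lt_row)
            hits = np.nonzero(best >= need)[0]
            for off in hits:
                j = i + 1 + off
                rows_a.append(genes[i])
                rows_b.append(genes[j])
                directions.append(A_GT_B if gt_row[off] >= lt_row[off] else A_LT_B)
                supports.append(best[off] / n_samples)

    pairs = pd.DataFrame(
        {
            "gene_a": rows_a,
            "gene_b": rows_b,
            "direction": directions,
            "support_fraction": supports,
        }
    )
    return StablePairSet(pairs, threshold, n_samples, phenotype_label, inclusive=inclusive)


def reversal_pairs(set1: StablePairSet, set2: StablePairSet) -> ReversalPairSet:
    """Pairs stable in both sets whose directions are opposite."""
    merged = set1.pairs.merge(
        set2.pairs, on=["gene_a", "gene_b"], suffixes=("_group1", "_group2")
    )
    rev = merged[merged["direction_group1"] != merged["direction_group2"]]
    out = rev.rename(
        columns={
            "support_fraction_group1": "support_group1",
            "support_fraction_group2": "support_group2",
        }
    )[
        ["gene_a", "gene_b", "direction_group1", "direction_group2", "support_group1", "support_group2"]
    ].reset_index(drop=True)
    return ReversalPairSet(out, set1.phenotype_label, set2.phenotype_label)
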