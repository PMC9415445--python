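"""Cross-platform construction of the reversal-pair signature.

The construction mirrors multi-platform discovery of a qualitative cancer
signature: per platform, find pairs stable in both phenotypes with opposite
orderings (reversal pairs); intersect the per-platform reversal sets keeping
only pairs reversed *the same way* on every platform; finally apply a
consistency filter that keeps pairs whose reference-phenotype ordering also
holds in more than a threshold fraction of an independent normal cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .reo import (
    ReversalPairSet,
    StablePairSet,
    opposite,
    reversal_pairs,
    stable_pairs,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Signature",
    "BuildReport",
    "intersect_reversal_sets",
    "consistency_filter",
    "build_signature",
    "unique_signature_genes",
    "write_signature",
    "read_signature",
]


@dataclass
class Signature:
    """The final reversal-pair signature.

    ``pairs`` columns: gene_a, gene_b, normal_direction, cancer_direction
    (each pair canonical, directions opposite by construction).
    """

    pairs: pd.DataFrame
    build_config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.pairs):
            key = self.pairs[["gene_a", "gene_b"]]
            if key.duplicated().any():
                raise ValueError("duplicate canonical pair in signature")
            same = self.pairs["normal_direction"] == self.pairs["cancer_direction"]
            if same.any():
                raise ValueError("signature pair with equal normal and cancer directions")

    def __len__(self) -> int:
        return len(self.pairs)

    def pair_keys(self) -> set[tuple[str, str]]:
        return set(zip(self.pairs["gene_a"], self.pairs["gene_b"]))


@dataclass
class BuildReport:
    """Pair counts surviving each construction stage, per platform and pooled."""

    per_platform_reversal: dict[str, int]
    n_intersection: int
    n_dropped_unmeasured: int
    n_signature: int


def intersect_reversal_sets(sets: list[ReversalPairSet]) -> ReversalPairSet:
    """Pairs reversed identically (same orientation in both groups) in every set."""
    if len(sets) < 2:
        raise ValueError("need at least two reversal sets to intersect")
    labels = {(s.group1_label, s.group2_label) for s in sets}
    if len(labels) != 1:
        raise ValueError(f"mismatched group labels across sets: {sorted(labels)}")
    current = sets[0].pairs
    for other in sets[1:]:
        current = current.merge(
            other.pairs[["gene_a", "gene_b", "direction_group1", "direction_group2"]],
            on=["gene_a", "gene_b", "direction_group1", "direction_group2"],
        )
    out = current.reset_index(drop=True)
    return ReversalPairSet(out, sets[0].group1_label, sets[0].group2_label)


def consistency_filter(
    candidates: ReversalPairSet,
    normal_matrix: pd.DataFrame,
    threshold: float = 0.9,
    *,
    strict: bool = True,
    reference_group: int = 1,
) -> Signature:
    """Keep candidates whose reference-phenotype direction holds in more than
    ``threshold`` (or at least, when ``strict`` is False) of the filter cohort.

    Pairs with either gene unmeasured on the filter platform are dropped with
    a logged count.  ``reference_group`` says which group of the reversal set
    is the reference (normal) phenotype.
    """
    if reference_group not in (1, 2):
        raise ValueError("reference_group must be 1 or 2")
    ref_col = f"direction_group{reference_group}"
    other_col = f"direction_group{3 - reference_group}"
    cand = candidates.pairs
    measured = cand["gene_a"].isin(normal_matrix.index) & cand["gene_b"].isin(normal_matrix.index)
    n_dropped = int((~measured).sum())
    if n_dropped:
        logger.info("consistency_filter: dropped %d pairs with unmeasured genes", n_dropped)
    cand = cand[measured]
    if cand.empty:
        raise ValueError("no candidate pair has both genes measured on the filter platform")

    values = normal_matrix
    keep_rows = []
    n_samples = values.shape[1]
    a_vals = values.loc[cand["gene_a"]].to_numpy()
    b_vals = values.loc[cand["gene_b"]].to_numpy()
    gt = (a_vals > b_vals).sum(axis=1) / n_samples
    lt = (a_vals < b_vals).sum(axis=1) / n_samples
    ref_support = pd.Series(
        [g if d == "a_gt_b" else l for g, l, d in zip(gt, lt, cand[ref_col])],
        index=cand.index,
    )
    ok = ref_support > threshold if strict else ref_support >= threshold
    surviving = cand[ok]
    if surviving.empty:
        raise ValueError(
            f"consistency filter removed every candidate "
            f"({len(cand)} candidates, threshold {threshold}, strict={strict})"
        )
    pairs = pd.DataFrame(
        {
            "gene_a": surviving["gene_a"].to_numpy(),
            "gene_b": surviving["gene_b"].to_numpy(),
            "normal_direction": surviving[ref_col].to_numpy(),
            "cancer_direction": surviving[other_col].to_numpy(),
        }
    ).reset_index(drop=True)
    return Signature(
        pairs,
        build_config={
            "filter_threshold": threshold,
            "filter_strict": strict,
            "filter_n_samples": n_samples,
            "n_dropped_unmeasured": n_dropped,
        },
    )


def build_signature(
    platform_cohorts: dict[str, dict[str, pd.DataFrame]],
    filter_cohort: pd.DataFrame,
    *,
    stability_threshold: float = 0.9,
    stability_inclusive: bool = True,
    consistency_threshold: float = 0.9,
    consistency_strict: bool = True,
    normal_label: str = "normal",
    cancer_label: str = "cancer",
) -> tuple[Signature, BuildReport]:
    """Orchestrate the full signature construction.

    ``platform_cohorts`` maps platform name -> {normal_label: matrix,
    cancer_label: matrix}.  ``filter_cohort`` is an independent matrix of the
    reference (normal) phenotype on a third platform.
    """
    if len(platform_cohorts) < 2:
        raise ValueError("need at least two discovery platforms")
    per_platform: list[ReversalPairSet] = []
    counts: dict[str, int] = {}
    for name, groups in platform_cohorts.items():
        for label in (normal_label, cancer_label):
            if label not in groups:
                raise ValueError(f"platform {name!r} missing phenotype {label!r}")
        stable_normal = stable_pairs(
            groups[normal_label],
            stability_threshold,
            inclusive=stability_inclusive,
            phenotype_label=normal_label,
        )
        stable_cancer = stable_pairs(
            groups[cancer_label],
            stability_threshold,
            inclusive=stability_inclusive,
            phenotype_label=cancer_label,
        )
        rev = reversal_pairs(stable_normal, stable_cancer)
        counts[name] = len(rev)
        logger.info("platform %s: %d reversal pairs", name, len(rev))
        per_platform.append(rev)

    intersection = intersect_reversal_sets(per_platform)
    logger.info("intersection: %d consistently reversed pairs", len(intersection))
    sig = consistency_filter(
        intersection,
        filter_cohort,
        consistency_threshold,
        strict=consistency_strict,
        reference_group=1,
    )
    sig.build_config.update(
        {
            "stability_threshold": stability_threshold,
            "stability_inclusive": stability_inclusive,
            "platforms": sorted(platform_cohorts),
            "normal_label": normal_label,
            "cancer_label": cancer_label,
        }
    )
    report = BuildReport(
        per_platform_reversal=counts,
        n_intersection=len(intersection),
        n_dropped_unmeasured=sig.build_config.get("n_dropped_unmeasured", 0),
        n_signature=len(sig),
    )
    logger.info("signature: %d pairs", len(sig))
    return sig, report


def unique_signature_genes(sig: Signature) -> list[str]:
    """Sorted deduplicated union of all member genes."""
    if not len(sig):
        return []
    return sorted(set(sig.pairs["gene_a"]) | set(sig.pairs["gene_b"]))


def write_signature(sig: Signature, path: str | Path) -> None:
    with open(path, "w") as handle:
        for key in sorted(sig.build_config):
            handle.write(f"# {key}={sig.build_config[key]}\n")
        sig.pairs.to_csv(handle, sep="\t", index=False)


def read_signature(path: str | Path) -> Signature:
    config: dict = {}
    with open(path) as handle:
        lines = handle.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            body_start = i + 1
            text = line[1:].strip()
            if "=" in text:
                key, _, raw = text.partition("=")
                config[key.strip()] = _parse_scalar(raw.strip())
        else:
            break
    from io import StringIO

    pairs = pd.read_csv(StringIO("".join(lines[body_start:])), sep="\t")
    return Signature(pairs, build_config=config)


def _parse_scalar(raw: str):
    for cast in (int, float):
        try:
            return cast(raw)
        except ValueError:
            pass
    if raw in ("True", "False"):
        return raw == "True"
    return raw
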