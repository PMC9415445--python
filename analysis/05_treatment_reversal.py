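#!/usr/bin/env python
"""Differential genes in the disease model and treatment-reversal frequency.

A six-replicate control / disease-model / four-treatment study is simulated
with 100 planted differential genes (log-scale effect 1.0); each treatment
pulls a random half of them fully back toward control.  Model-vs-control
genes at p < 0.05 (pooled t-test, df = 10) are then counted across
treatments at p thresholds 0.05 / 0.1 / 0.2, and the counts are compared
between genes with and without a planted reversal.

Writes: results/05_model_vs_control.tsv, results/05_reversal_frequency.tsv
"""

import argparse
from pathlib import Path

import pandas as pd

from reosig.de import treatment_reversal_table, two_group_stats
from reosig.synthetic import TreatmentConfig, simulate_treatment_study

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 7) -> None:
    cfg = TreatmentConfig(seed=seed)
    study = simulate_treatment_study(cfg)

    mvc = two_group_stats(study.model, study.control)
    significant = mvc[mvc["p"] < 0.05]
    truth_hits = significant.index.isin(study.truth_de_genes)

    treatment_stats = {
        name: two_group_stats(matrix, study.model)
        for name, matrix in study.treatments.items()
    }
    table = treatment_reversal_table(mvc, treatment_stats)

    reversed_any = set().union(*study.truth_reversed.values())
    planted = table.index.isin(reversed_any)
    mean_rev = table.loc[planted, "num_p_lt_0.05"].mean()
    mean_non = table.loc[~planted, "num_p_lt_0.05"].mean()

    RESULTS.mkdir(exist_ok=True)
    significant.sort_values("p").to_csv(
        RESULTS / "05_model_vs_control.tsv", sep="\t", index=False
    )
    table.to_csv(RESULTS / "05_reversal_frequency.tsv", sep="\t", index=False)

    print(f"model vs control: {len(significant)} genes at p<0.05 "
          f"({truth_hits.sum()} of {len(study.truth_de_genes)} planted, "
          f"{len(significant) - truth_hits.sum()} false positives)")
    print(f"mean treatments with p<0.05: {mean_rev:.2f} for planted-reversed "
          f"genes vs {mean_non:.2f} for non-reversed differential genes")
    print(table.head(8).to_string(index=False))


if __name__ == "__main__":
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=7)
    main(parser.parse_args().seed)
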