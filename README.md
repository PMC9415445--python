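# reosig

Rank-based (relative expression ordering) transcriptional signatures for
cancer-risk assessment, with a full synthetic-cohort test bed.

## The problem

Quantitative expression signatures travel badly between laboratories:
scanner, protocol and normalisation differences (batch effects) shift the
measured intensities, so a threshold learned on one dataset is meaningless
on another. *Relative expression orderings* (REOs) sidestep this: for two
genes A and B measured in the **same** sample, whether A > B is unchanged by
any strictly increasing per-sample transformation, which is how most batch
effects act. Signatures built from within-sample orderings can therefore be
applied to a single sample from any platform without renormalisation.

`reosig` implements the REO workflow used to assess lung-cancer
incidence-risk in patients with chronic obstructive pulmonary disease
(COPD):

1. **Stable pairs** — a gene pair (A, B) is stable in a phenotype when one
   ordering holds in at least a threshold fraction θ (default 90%) of that
   phenotype's samples.
2. **Reversal pairs** — pairs stable in both phenotypes with opposite
   orderings; discovered per platform, intersected across platforms
   (requiring identical orientation), then filtered against an independent
   normal cohort (ordering in > 90% of samples).
3. **Incidence-risk score** — for one sample, with *m* evaluable signature
   pairs of which *n* show the cancer-characteristic ordering, the score is
   *n/m* ∈ [0, 1]; score > ½ (majority vote) calls the sample cancer-like.
4. **Stage correlation** — each pair's per-sample cancer-ordering indicator
   is correlated with ordinal disease stage (Spearman ρ, Benjamini–Hochberg
   FDR); lists from independent cohorts are compared with the upper-tail
   hypergeometric probability
   P(X ≥ k) = Σ_{i≥k} C(m,i)·C(N−m,n−i)/C(N,n),
   which also powers pathway enrichment over GMT gene sets.
5. **Treatment reversal** — pooled-variance Student t statistics
   (df = n₁+n₂−2) for disease-model vs control, and per-gene counts of
   treatment arms whose treatment-vs-model p-value falls below
   0.05 / 0.1 / 0.2.

Because the original microarray cohorts are external, the package ships a
first-class synthetic generator (`reosig.synthetic`) that plants reversal
pairs, multiple platforms, monotone per-sample batch distortions, stage
gradients and treatment effects with known ground truth.

## Worked example

The numbered scripts under `analysis/` run the whole pipeline on synthetic
cohorts and write their tables under `results/`. Building the signature at
the default study conditions (1000 genes, 200 planted pairs, 50 samples per
group, log-ratio gap 2, noise SD 1, two discovery platforms plus one filter
cohort, batch distortion on):

```bash
$ python analysis/02_build_signature.py --seed 7
                  stage  n_pairs
     reversal_platform1      199
     reversal_platform2      200
consistent_intersection      199
        final_signature      197
          planted_truth      200

recall of planted pairs:  0.985
contamination:            0.000
```

197 of the 200 planted pairs survive all three construction stages and no
spurious pair enters the signature. Scoring the held-out cohort:

```bash
$ python analysis/03_score_and_classify.py --seed 7
           count       50%       min       max
phenotype
cancer      50.0  0.974619  0.949239  1.000000
normal      50.0  0.017766  0.000000  0.050761

AUC 1.0000 (95% CI 1.0000-1.0000); sensitivity 100.00%, specificity 100.00%
scores invariant under monotone distortion: True
```

Cancer-like samples score near 1 (almost every signature pair flipped),
normal samples near 0, and every score is bit-identical after a random
strictly-monotone per-sample distortion — the batch-invariance the method
is built on. `04_stage_enrichment.py` and `05_treatment_reversal.py`
continue with the stage-correlation and treatment-reversal analyses.

The same operations are available as a CLI (`reosig simulate`,
`build-signature`, `score`, `stage`, `enrich`, `de`) for use on real
TSV/GMT inputs; run `reosig --help`.

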