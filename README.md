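# ebrisk

Empirical-Bayes risk prediction for rare-variant exome data.

The package implements a shrunken linear-discriminant pipeline for
case-control data with gene-level rare-variant burden scores:

1. **Gene scores** — Madsen-Browning weighted burden per gene
   (`ebrisk.gene_scores`), optionally restricted to synonymous or
   nonsynonymous SNPs.
2. **Z statistics** — per-replicate two-sample Z per gene, aggregated over
   phenotype replicates with an exchangeable-correlation correction
   (`ebrisk.zstats`).
3. **Empirical-Bayes shrinkage** — the marginal density of the z-values is
   fitted by Lindsey's method (Poisson regression of histogram counts on a
   polynomial with log link) and per-gene effects are estimated by Tweedie's
   formula, `delta_hat(z) = z + d/dz log f(z)` (`ebrisk.eb_shrink`).
4. **Classifiers** — three prediction rules built on the shrunken effects
   (`ebrisk.classifiers`):
   - `eb`: diagonal LDA over all-SNP gene scores;
   - `web`: weighted EB — each gene's synonymous and nonsynonymous channel
     scores are combined with a data-driven weight from logistic-regression
     p-values;
   - `jc`: joint covariance — both channels kept as a bivariate feature with
     a per-gene 2x2 within-class correlation matrix and separate shrinkage
     of the two channel populations.
   Covariates (Age, Sex, Smoke) enter unshrunk through a logistic linear
   predictor; class imbalance sets the decision threshold.
5. **Selection & evaluation** — replicate-split cross-validation chooses the
   number of genes by test-set misclassification error and reports
   validation error and ROC/AUC (`ebrisk.selection_eval`).
6. **Synthetic data** — a mini-exome generator with a rare-skewed MAF
   spectrum, liability-threshold phenotype replicates redrawn on fixed
   genotypes, and known ground truth (`ebrisk.synthetic`).

## Tests

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (shrinkage
correctness in the conjugate limit, MSE dominance, correlation recovery,
oracle equivalence with brute-force diagonal LDA, algebraic reductions,
null calibration, signal recovery, and the WEB-over-EB ordering when only
nonsynonymous SNPs are causal).

## Command line

Every stage is a subcommand writing inspectable TSV/JSON plus a provenance
record:

```sh
ebrisk simulate --config sim.yaml --out data/        # synthetic dataset
ebrisk score    --data data/ --out scores/           # burden scores
ebrisk zstats   --data data/ --out z/                # Z, rho, z*
ebrisk fit      --data data/ --model web --k 10 --out rule/
ebrisk predict  --data data/ --rule rule/rule.json --out pred/
ebrisk evaluate --predictions pred/predictions.tsv --data data/ --out eval/
ebrisk cv       --data data/ --model jc --k-grid 1,2,5,10 \
                --splits 8,6,6 --n-splits 5 --seed 1 --out cv/
```

Input layout (tab-separated, one header row each):

| file | header |
|---|---|
| `genotypes.tsv` | `sample_id`, then one column per SNP (values 0/1/2) |
| `annotation.tsv` | `snp_id`, `gene_id`, `class` (synonymous/nonsynonymous) |
| `phenotypes.tsv` | `sample_id`, then one binary column per replicate |
| `covariates.tsv` | `sample_id`, `Age`, `Sex`, `Smoke`, ... |

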