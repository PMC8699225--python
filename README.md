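# polygs

Genomic selection for autopolyploid crops with SNP-weighted GBLUP.

`polygs` implements the full weighted-GBLUP workflow for autotetraploid
breeding data: allele-dosage genotype handling (VCF or delimited
matrices, coded `0..ploidy`), four genomic relationship matrix (GRM)
constructions, REML variance components with GBLUP/RRBLUP prediction of
genomic estimated breeding values (GEBVs), a kinship-corrected
single-marker association scan over eight dosage gene-action models
whose `-log10 p` scores (or ML variable importances) become per-marker
weights in a diagonal `D` matrix, and a repeated cross-validation
harness that compares prediction accuracy across model configurations.
A simulator for tetraploid panels with controlled QTL architecture and
heritability makes the whole pipeline runnable with no external data.

## Modules

| module | what it does |
| --- | --- |
| `polygs.dosage_io` | VCF/CSV genotype and phenotype I/O, mean imputation, MAF filter, pseudodiploid recode, genotype-class one-hot expansion |
| `polygs.grm` | GRM builders: centered cross-product (VanRaden-style), allele-frequency-weighted diploid (Yang-style), full-autotetraploid indicator (Slater-style), and the SNP-weighted `G* = Z D Z' / c` |
| `polygs.mixed_model` | eigendecomposition-based REML (exact 1-D profile in the variance ratio), GBLUP prediction, ridge marker-effect solver |
| `polygs.gwas_scan` | P3D association scan under additive / diploidized / simplex- and duplex-dominant / general dosage codings; score-to-weight conversion; weight correlations |
| `polygs.cv_harness` | repeated k-fold CV with paired folds, `nested` vs `mimic_paper` weight-leakage modes, ranked comparison tables |
| `polygs.polysim` | synthetic tetraploid genotypes (binomial dosages, optional LD blocks) and phenotypes with per-QTL gene actions at a target heritability |
| `polygs.importance` | permutation-importance weights from scikit-learn baselines (RF, SVR) |
| `polygs.cli` | `polygs` command-line pipeline |

## Command line

```sh
# synthetic dataset: 300 individuals x 2000 markers, 5 major QTL, h2=0.5
polygs simulate --n 300 --m 2000 --n-qtl 5 --h2 0.5 --seed 1 --out runs/sim

# GRM, association scan, SNP weights
polygs grm  --genotypes runs/sim/genotypes.csv --method vanraden --out runs/G.csv
polygs scan --genotypes runs/sim/genotypes.csv --phenotypes runs/sim/phenotypes.csv \
            --models additive,general --out runs/scan.csv
polygs weights --genotypes runs/sim/genotypes.csv --phenotypes runs/sim/phenotypes.csv \
            --model additive --out runs/w.csv

# cross-validated accuracy: plain GBLUP vs weighted GBLUP
polygs wgblup --genotypes runs/sim/genotypes.csv --phenotypes runs/sim/phenotypes.csv \
            --weight-source uniform --weight-source gwas:additive \
            --k 10 --repeats 10 --seed 7 --out runs/cv
polygs cv-report --run-dir runs/cv
```

Every run directory contains a `manifest.json` (config hash, seeds,
input digests, version); identical seeds reproduce identical numeric
outputs. YAML config files can override flags via `--config`.

## Modeling notes

- The weighted GRM with unit weights reduces exactly to the unweighted
  centered cross-product GRM; this identity is tested to 1e-12.
- The printed formulation calls `Z` "an identity matrix for the
  markers"; taken literally the quadratic form is degenerate, so `Z` is
  interpreted as the column-centered dosage matrix (the standard
  construction). Two denominators are available: `ploidy_scaled`
  (`phi * sum(p(1-p))`, unit expected diagonal for dosages `0..phi`,
  default) and `paper_literal` (`2 * sum(p(1-p))`).
- Weights are normalized to mean one before entering `D` by default so
  `tr(G*)` stays comparable to `tr(G)`.
- CV reports always carry the leakage mode; `mimic_paper` (weights from
  the full data) is provided for comparability but is labeled as such.
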