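# layerqtl

QTL mapping and QTL-by-environment interaction analysis for **daughter
designs** in layer chickens: genotyped sires, phenotyped crossbred
daughters housed twelve half-sisters to a cage, cages split between a
high-energy (HE) and a low-energy (LE) diet, and egg-quality traits
collected at 50 and 70 weeks of age.

The package is aimed at quantitative geneticists who want a tested,
reusable implementation of this analysis — and a synthetic-data
generator that reproduces its statistical structure, since real
600K-genotype/farm-phenotype datasets of this kind are rarely public.

## What it computes

1. **SNP quality control** — five sequential filters (low-call markers,
   individual call rate, MAF, marker call rate, Hardy–Weinberg
   chi-square) with a reconciling exclusion ledger.
2. **Phenotype adjustment** — per-hatch fixed-effect models
   (sire, diet, age class, cage location, operator, covariates), a
   p < 0.2 screening sub-model, adjustment for every retained non-sire
   effect, 4-SD outlier trimming, and per-sire means of the adjusted
   daughter records ("sire performances"), overall and per condition.
3. **Pedigree kinship** — the additive relationship matrix **A** by the
   recursive tabular method.
4. **Mixed-model GWAS** — for each SNP and trait,

   Z = 1μ + Xα + E,  V(E) = **A**σ²g + **I**σ²e,

   where Z holds the sire performances, X the sire minor-allele
   dosages, and α is the allele substitution effect. σ²g and σ²e are
   REML estimates of the null model (one eigendecomposition of **A**,
   reused for every marker); chromosome-wide 1 % thresholds come from
   Monte-Carlo calibration of the per-chromosome maximum statistic and
   genome-wide thresholds from the Bonferroni rule across chromosomes.
5. **QTL calling** — a QTL per run of chromosome-wide-significant SNPs
   containing a genome-wide-significant one; confidence interval = the
   run, top SNP = largest |α̂|, variance explained = 2p(1−p)α² divided
   by the variance of the sire performances; overlapping intervals are
   merged into one catalogue identity across traits.
6. **QTL × environment tests** — per-condition re-estimation of each
   top-SNP effect (α₁, α₂), a Fisher test on the residual variances, the
   interaction statistic

   Z = |α₁ − α₂| / σ × √n,

   (σ² the average residual variance, n the average sire count),
   classification into sign inversions vs magnitude changes, and
   within-condition scans that recover "additional QTL" whose effects
   cancel in the pooled data.

## Worked example

`examples/04_gxe_interaction.py` plants a QTL with opposite effects
under the two diets (α_HE = +4, α_LE = −4 trait units) and no marginal
effect, on a simulated 300-sire design:

```
whole-data scan: 0 QTL (the planted one has no marginal effect)
within-diet scans: 1 additional QTL
  ADD1: alpha_HE=+1.39, alpha_LE=-1.87, Z=23.81*** -> sign_inversion

HE/LE correlation of sire performances: r=0.42 over 300 sires
```

The pooled scan finds nothing because the two diet effects cancel; the
within-diet scans recover the locus, the per-diet allele substitution
effects have opposite signs (sires transmit half their dosage, so the
sire-mean-scale effects are about ±α/2 of the planted daughter-scale
values), the Z test stars it at p < 0.01, and the antagonistic locus
drags the between-diet correlation of sire performances down from its
polygenic ceiling.

The other example scripts cover the generator itself (`01`), QC and the
derived egg-trait formulas (`02`), the mixed-model scan and QTL calling
(`03`), and the one-call `run_pipeline` orchestration with TSV
artifacts and a byte-reproducibility manifest (`05`).

## Layout

- `src/layerqtl/` — `simulate`, `qc`, `adjust`, `kinship`, `gwas`,
  `qtl`, `gxe`, `io`, `pipeline`
- `examples/` — one narrative script per capability
- `docs/methods.md` — model details, parameter choices, limitations
- `tests/` — unit, property and end-to-end suites
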