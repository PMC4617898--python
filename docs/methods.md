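# Methods

This note records the statistical model the package implements, the
design choices that were genuinely open, the numerical details, and
what the synthetic-data generator does and does not emulate.

## The daughter design

Sires from a pure line are genotyped; phenotypes are recorded on their
crossbred daughters, housed in collective cages of twelve half-sisters
of the same sire. Half of the cages receive a high-energy (HE) diet and
half a low-energy (LE) diet; egg-quality traits are measured on eggs
collected around 50 and 70 weeks of age, egg-production traits are
recorded at cage level over defined laying periods. The unit of
association analysis is the *sire performance*: the mean of a sire's
daughters' environment-adjusted records, computed over the whole data
and within each of the four conditions (HE, LE, 50 wk, 70 wk).

## Phenotype adjustment

Within each hatch, each trait is fitted by ordinary least squares with
sire always in the model plus candidate environment terms — diet,
battery (4 levels), column (2), floor (2) for cage-level production
traits; additionally age class (50/70), operator, and the covariates W
(days between collection and measurement) and R (hen age in days) for
egg-level quality traits. Terms with a Type-II F-test p-value below the
screening level (default 0.2) are retained and the sub-model refitted.
Type II was chosen for invariance to term order; coding is
reference-level (first level as reference), recorded in the fit
metadata.

An adjusted record is the fitted sire effect (centred over the hatch's
records) plus the residual — equivalently, the raw value minus every
retained non-sire effect, with covariates acting around their hatch
means so the adjusted trait keeps a stable location. With no retained
environment terms this reduces to raw minus the hatch grand mean, which
also removes hatch-level differences when hatches are pooled. Records
more than 4 phenotypic SD from the adjusted-trait mean (per trait, per
hatch) are discarded once, after adjustment; trimming at the boundary
retains (strictly "more than").

## Kinship

The additive relationship matrix A is built by the recursive tabular
method (a_ii = 1 + F_i, a_ij averaged over parents, unknown parents
contributing zero), on the genotyped sires plus all their recorded
ancestors, then sub-selected to the sires. Dense storage is deliberate:
the design has hundreds of sires. Agreement with a gene-dropping
Monte-Carlo oracle and positive semi-definiteness are enforced by
tests.

## Mixed-model scan

Per trait and condition the null model Z = 1μ + E with
V(E) = Aσ²g + Iσ²e is fitted by REML. The implementation
eigendecomposes A once, rotates the data, and maximises the restricted
likelihood over the ratio h = σ²g/(σ²g + σ²e) by bounded scalar
optimisation, profiling the total variance analytically; components are
clipped at zero and a constant phenotype is flagged degenerate. The
eigendecomposition and the fitted components are then reused for every
marker (the EMMAX strategy): each marker's allele substitution effect
is the GLS slope of the sire means on minor-allele dosage with V held
fixed, and the Wald statistic is referred to the standard normal.
Re-estimating variance components per SNP would add nothing at this
sample size and is computationally implausible at 284k markers.

Markers with missing dosages drop the affected sires and solve against
the sub-covariance by Cholesky factorisation, grouped by missingness
pattern; markers monomorphic among the used sires are flagged and not
tested.

## Significance thresholds

Chromosome-wide 1 % thresholds are calibrated by Monte Carlo: under the
global null the per-marker Wald statistics are jointly normal with
correlation equal to that of the GLS-whitened, intercept-residualised
genotype columns, so draws of the whole vector are obtained by
projecting iid normal noise onto those columns; the threshold is the
level-quantile of the per-draw minimum p-value. This honours the
correlation between markers (duplicated markers cost nothing; independent
markers approach the Šidák limit). A plain per-chromosome Bonferroni
fallback is available. Genome-wide thresholds run the same machinery at
level 0.05/n_chromosomes, with n_chromosomes defaulting to the number
of chromosome labels analysed. Because a genome-wide-significant SNP
must anchor a chromosome-wide run (the QTL interval definition), the
genome level is capped at the chromosome level; with ~32 chromosomes
the cap never binds. Markers without a chromosome assignment get a
plain Bonferroni level 0.05/m over their group.

## QTL calling and variance explained

Per chromosome, each maximal run of chromosome-wide-significant markers
(gap tolerance 0 by default) containing at least one
genome-wide-significant marker is one QTL; the confidence interval is
the closed span of the run, and the top SNP is the run's largest |α̂| —
absolute value, because a signed maximum would be arbitrary under
minor-allele coding. Variance explained is 100·2p(1−p)α²/var(sire
performances), with p the top SNP's MAF and the variance taken over the
sire means actually scanned for that trait and condition. QTL whose
intervals overlap on a chromosome are merged into one catalogue
identity by transitive union, with deterministic ids ordered by
chromosome (numeric labels first) then interval start.

## Interaction tests

For each QTL and factor (diet, age) the top-SNP effect is re-estimated
within each condition by the same scan machinery. The interaction
statistic is implemented literally as

    Z = |α₁ − α₂| / σ × √n

with σ² the mean of the two conditions' null-model residual variances
(σ²e) and n the mean sire count, referred to the standard normal. This
formula omits both the √2 of a difference of two independent estimates
and the genotype-variance scaling of a regression slope's sampling
variance, so it is **anti-conservative**: in our simulations at n = 300
and MAF 0.3 its empirical null rejection rate at nominal 0.01 is around
0.15 (stable across seed batches, and power is monotone in |α₁ − α₂|).
The package therefore documents rather than assumes its calibration,
and offers a variance-correct Wald contrast |α₁ − α₂|/√(SE₁² + SE₂²)
behind `variant="wald"` for calibration studies. The within-condition
residual variances are also compared by a two-sided Fisher F test, the
equality assumption behind pooling them.

Significant interactions (loosest star level, p < 0.1, configurable)
are classified *sign inversion* if the two effects have opposite signs
and *magnitude change* otherwise. Additional QTL are found by running
the full scan-and-call machinery within each condition and flagging
catalogue intervals that overlap no whole-data QTL.

## Synthetic-data generator

The generator emulates the study design: by default 438 sires with 72
daughters each in cages of 12 half-sisters, cages alternating between
the diets (so each sire's daughters split evenly), three hatches,
quality traits recorded per daughter at both collection ages and
production traits per cage. Trait values are sums of a per-trait
polygenic value (daughter = half the sire value + Mendelian sampling),
centred planted-QTL contributions, fixed environment effects drawn once
per dataset (magnitudes specified per factor in trait-SD units;
defaults 0.05–0.15 SD), covariate terms, and Gaussian residuals. The
default 16-trait panel uses the published HE-diet 50-week means and
phenotypic SDs with a 30/70 polygenic/residual split (moderate
heritability typical of egg traits). The blood/meat-spot score is
generated by rounding a latent Gaussian to the 0–3 scale and analysed
as numeric.

Daughters are not genotyped: at a planted QTL the daughter receives one
sire allele with probability dosage/2 and one allele from an unrelated
dam pool segregating at the marker's frequency, so the regression of
sire means on sire dosage has slope α/2. Dosage columns are folded to
the *observed* minor allele (exactly as the PED/VCF readers fold), so
written genotypes round-trip bit for bit and the planted α always
refers to the counted allele.

Sires are grouped into paternal half-sib families under ungenotyped
grandsires (default ~10 sires per family); without such structure A
restricted to the sires is the identity and σ²g/σ²e are not separable.
Marker genotypes are drawn independently of the pedigree — the
polygenic term alone carries the relatedness — and no linkage
disequilibrium, hatch seasonality, or 600K-scale density is simulated.
Consequently, passing tests demonstrate the estimators' behaviour under
the assumed model (independent markers, additive effects, Gaussian
residuals), not robustness to LD structure, selection, or non-additive
inheritance in real data. All randomness descends from a single seed
through a splittable generator; identical configurations reproduce
datasets bit for bit.

## Derived-trait formulas

Two published index formulas are internally inconsistent with the
summary statistics they accompany, so both variants are implemented
(see the module docstring of `layerqtl.traits`): the shape index
defaults to the table-consistent SLE/(10·EW^(1/3)) (the printed variant
is behind a flag), the shell-colour index defaults to the printed
100 − (L* − a* − b*) (the table-consistent variant behind a flag). The
Haugh unit uses the standard base-10 logarithm. Egg production rate is
100 × eggs/hen-days over closed week windows 18–75 (EPR), 18–30 (EPR1),
31–49 (EPR2), 50–75 (EPR3).

## Quality-control details

Call rates and MAF are computed over the current surviving set, MAF
from non-missing dosages only; step 1 is a generic "call rate < 5 %"
marker filter (the motivating case being W-chromosome probes assayed in
ZZ males). The Hardy–Weinberg test is the 1-df chi-square at the
observed allele frequency (the asymptotic test is standard at n ≈ 440);
a conditional exact test is provided but off by default. The
term-screening rule retains effects with p < 0.2 — the literal reading
"exceeding 0.2" would keep only noise. Sequential filtering is
idempotent whenever no individual sits exactly at the call-rate
boundary after marker removal.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale — hundreds of sires,
tens to thousands of markers, 20-replicate Monte-Carlo experiments —
chosen so the whole suite completes in minutes while keeping the
statistical checks informative (3-SE bands, binomial error on
rejection rates, KS at 1 %). Threshold calibration uses 2,000–20,000
draws depending on the level; the REML optimiser uses a bounded search
on h ∈ [10⁻⁶, 1−10⁻⁶] with an explicit boundary check at h = 0;
eigenvalues of A are clipped at zero against round-off. Determinism is
part of every contract: configuration + seed reproduces all artifacts
byte for byte (SHA-256 manifest).

## Known limitations

- No LD, no genomic relationship matrix, no dominance or epistasis —
  deliberately out of scope.
- The literal interaction Z statistic is anti-conservative (see above);
  its published star levels should be read as a ranking device rather
  than calibrated error rates.
- The 1-df chi-square HWE filter is asymptotic; at very low MAF the
  exact-test option is preferable (MAF < 0.05 markers are removed
  before the HWE step in the default pipeline anyway).
- Sequential QC is order-faithful to the published pipeline; exclusion
  counts are therefore not comparable to single-pass filtering.
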