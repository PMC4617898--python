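"""QTL-by-environment interaction tests.

Each QTL's top-SNP allele substitution effect is re-estimated within
each condition (HE vs LE diet; 50 vs 70 weeks of age) and the two
estimates ``alpha_1`` and ``alpha_2`` are compared with

* a two-sided Fisher F test on the within-condition residual variances
  (equality of which the Z test assumes), and
* the Z statistic ``Z = |alpha_1 - alpha_2| / sigma * sqrt(n)``, with
  ``sigma^2`` the average residual variance and ``n`` the average sire
  count over the two conditions, referred to the standard normal.

The Z formula is implemented literally as the default. It omits both
the sqrt(2) of a difference of two independent estimates and the
genotype-variance scaling of a regression slope's sampling variance, so
its nominal calibration should not be assumed; a variance-correct Wald
contrast ``|alpha_1 - alpha_2| / sqrt(se_1^2 + se_2^2)`` is available
via ``variant="wald"`` for calibration studies.

Significant interactions are classified as a *sign inversion* (the
allele effect reverses direction between conditions, typical of
production traits) or a *magnitude change* (same direction, different
size, typical of quality traits).

QTL that the whole-data scan misses but a within-condition scan finds
("additional QTL") are detected by running the full scan/call machinery
per condition and flagging catalogue intervals that do not overlap any
whole-data QTL.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gwas import MixedModelScan, VarianceComponents, compute_thresholds
from .qtl import QTLRecord, call_qtls, merge_across_traits

__all__ = ["InteractionResult", "fisher_variance_test", "z_interaction",
           "classify_interaction", "significance_stars",
           "within_condition_scan_and_augment", "condition_correlations"]

#: Default star levels, loosest first.
STAR_LEVELS = ((0.01, "***"), (0.05, "**"), (0.1, "*"))


@dataclass
class InteractionResult:
    qtl_id: str
    trait: str
    factor: str                 # "diet" or "age"
    condition1: str
    condition2: str
    alpha1: float
    alpha2: float
    sigma2_avg: float
    n_avg: float
    fisher_f: float
    fisher_p: float
    z: float
    p: float
    stars: str
    interaction_class: str      # sign_inversion | magnitude_change | none


def fisher_variance_test(s1_sq: float, df1: int, s2_sq: float,
                         df2: int) -> tuple[float, float]:
    """Two-sided F test of equality of two variances.

    F is the larger over the smaller variance; the two-sided p-value is
    twice the upper-tail probability, capped at 1.
    """
    if s1_sq <= 0 or s2_sq <= 0:
        raise ValueError("variances must be positive")
    if df1 < 1 or df2 < 1:
        raise ValueError("degrees of freedom must be >= 1")
    if s1_sq >= s2_sq:
        f, dfn, dfd = s1_sq / s2_sq, df1, df2
    else:
        f, dfn, dfd = s2_sq / s1_sq, df2, df1
    p = min(1.0, 2.0 * float(stats.f.sf(f, dfn, dfd)))
    return float(f), p


def z_interaction(alpha1: float, alpha2: float, sigma2_avg: float,
                  n_avg: float, *, variant: str = "literal",
                  se1: float | None = None,
                  se2: float | None = None) -> tuple[float, float]:
    """Interaction Z statistic and two-sided normal p-value.

    ``variant="literal"`` (default) computes
    ``Z = |alpha_1 - alpha_2| / sigma * sqrt(n)`` exactly as published;
    ``variant="wald"`` computes the variance-correct contrast
    ``|alpha_1 - alpha_2| / sqrt(se_1^2 + se_2^2)`` and requires the two
    standard errors.
    """
    if variant == "literal":
        if sigma2_avg <= 0:
            raise ValueError("average residual variance must be positive")
        if n_avg < 2:
            raise ValueError("average sire count must be >= 2")
        z = abs(alpha1 - alpha2) / np.sqrt(sigma2_avg) * np.sqrt(n_avg)
    elif variant == "wald":
        if se1 is None or se2 is None:
            raise ValueError("wald variant requires se1 and se2")
        z = abs(alpha1 - alpha2) / np.sqrt(se1**2 + se2**2)
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return float(z), float(2.0 * stats.norm.sf(z))


def significance_stars(p: float, levels=STAR_LEVELS) -> str:
    for cut, stars in sorted(levels):
        if p < cut:
            return stars
    return ""


def classify_interaction(alpha1: float, alpha2: float,
                         significant: bool) -> str:
    """Direction of a significant interaction.

    ``sign_inversion`` when the two effects have opposite signs (either
    may be zero only on one side), ``magnitude_change`` otherwise;
    ``none`` when the interaction is not significant.
    """
    if not significant:
        return "none"
    if np.sign(alpha1) != np.sign(alpha2):
        return "sign_inversion"
    return "magnitude_change"


@dataclass
class ConditionScan:
    """Everything the interaction tests need from one condition's scan."""
    condition: str
    vc: VarianceComponents
    results: pd.DataFrame
    n_sires: int
    var_sire: float
    qtls: list[QTLRecord]


def _scan_condition(scanner: MixedModelScan, genotypes, means: pd.DataFrame,
                    trait: str, condition: str, *, chrom_level, genome_alpha,
                    n_chromosomes, unknown_chrom, n_draws, seed,
                    threshold_method) -> ConditionScan:
    sub = means[(means["trait"] == trait) & (means["condition"] == condition)]
    sub = sub.set_index("sire").reindex(scanner.ids)
    if sub["mean"].isna().any():
        missing = sub.index[sub["mean"].isna()][:5].tolist()
        raise ValueError(f"no {condition} sire means for sires {missing}")
    y = sub["mean"].to_numpy(float)
    vc = scanner.fit_null_reml(y, trait, condition)
    results = scanner.scan(y, genotypes.dosages, genotypes.markers, vc)
    thresholds = compute_thresholds(
        scanner, genotypes, vc, chrom_level=chrom_level,
        genome_alpha=genome_alpha, n_chromosomes=n_chromosomes,
        unknown_chrom=unknown_chrom, n_draws=n_draws, seed=seed,
        method=threshold_method)
    var_sire = float(np.var(y, ddof=1))
    qtls = call_qtls(results, thresholds, trait=trait, condition=condition,
                     var_sire=var_sire)
    return ConditionScan(condition, vc, results, len(y), var_sire, qtls)


def _alpha_at(results: pd.DataFrame, marker: str) -> tuple[float, float]:
    row = results.loc[results["marker"] == marker]
    if row.empty:
        return np.nan, np.nan
    return float(row["alpha"].iloc[0]), float(row["se"].iloc[0])


def _interaction_for(qtl: QTLRecord, factor: str, c1: "ConditionScan",
                     c2: "ConditionScan", *, variant: str,
                     class_alpha: float) -> InteractionResult:
    a1, se1 = _alpha_at(c1.results, qtl.top_marker)
    a2, se2 = _alpha_at(c2.results, qtl.top_marker)
    s1, s2 = c1.vc.sigma2_e, c2.vc.sigma2_e
    df1, df2 = c1.n_sires - 2, c2.n_sires - 2
    if s1 > 0 and s2 > 0:
        f, fp = fisher_variance_test(s1, df1, s2, df2)
    else:
        f, fp = np.nan, np.nan
    sigma2_avg = 0.5 * (s1 + s2)
    n_avg = 0.5 * (c1.n_sires + c2.n_sires)
    z, p = z_interaction(a1, a2, sigma2_avg, n_avg, variant=variant,
                         se1=se1, se2=se2)
    stars = significance_stars(p)
    cls = classify_interaction(a1, a2, p < class_alpha)
    return InteractionResult(
        qtl_id=qtl.qtl_id or "", trait=qtl.trait, factor=factor,
        condition1=c1.condition, condition2=c2.condition,
        alpha1=a1, alpha2=a2, sigma2_avg=sigma2_avg, n_avg=n_avg,
        fisher_f=f, fisher_p=fp, z=z, p=p, stars=stars,
        interaction_class=cls)


FACTOR_PAIRS = {"diet": ("HE", "LE"), "age": ("AGE50", "AGE70")}


def within_condition_scan_and_augment(
        means: pd.DataFrame, genotypes, A, *, trait: str,
        whole_qtls: list[QTLRecord],
        chrom_level: float = 0.01, genome_alpha: float = 0.05,
        n_chromosomes: int | None = None, unknown_chrom: str | None = None,
        n_draws: int = 5_000, seed: int = 0,
        threshold_method: str = "montecarlo",
        variant: str = "literal", class_alpha: float = 0.1,
        scanner: MixedModelScan | None = None,
) -> tuple[list[QTLRecord], list[InteractionResult]]:
    """Per-condition scans, additional-QTL discovery and interaction tests.

    Runs the full mixed-model scan and QTL-calling machinery on each
    within-condition set of sire means present in ``means`` for
    ``trait``, flags QTL whose interval overlaps no whole-data QTL as
    *additional*, and returns an :class:`InteractionResult` per factor
    for every QTL (whole-data and additional).

    ``class_alpha`` is the significance level used both for starring the
    loosest level and for deciding whether to classify the interaction
    (default 0.1, the loosest reported star level).
    """
    scanner = scanner or MixedModelScan(A)
    scans: dict[str, ConditionScan] = {}
    for factor, (cond1, cond2) in FACTOR_PAIRS.items():
        have = set(means.loc[means["trait"] == trait, "condition"])
        if not {cond1, cond2} <= have:
            continue
        for k, cond in enumerate((cond1, cond2)):
            scans[cond] = _scan_condition(
                scanner, genotypes, means, trait, cond,
                chrom_level=chrom_level, genome_alpha=genome_alpha,
                n_chromosomes=n_chromosomes, unknown_chrom=unknown_chrom,
                n_draws=n_draws, seed=seed + 1000 * len(scans),
                threshold_method=threshold_method)

    # additional QTL: per-condition catalogue entries not overlapping a
    # whole-data QTL interval
    condition_qtls = [q for s in scans.values() for q in s.qtls]
    additional: list[QTLRecord] = []
    if condition_qtls:
        merge_across_traits(condition_qtls)  # stamps provisional ids
        seen: set[str] = set()
        for q in condition_qtls:
            if any(q.overlaps(w) for w in whole_qtls):
                continue
            if q.qtl_id in seen:
                continue
            seen.add(q.qtl_id)
            additional.append(q)
        for i, q in enumerate(additional, start=1):
            q.qtl_id = f"ADD{i}"

    results: list[InteractionResult] = []
    for factor, (cond1, cond2) in FACTOR_PAIRS.items():
        if cond1 not in scans or cond2 not in scans:
            continue
        for q in list(whole_qtls) + additional:
            results.append(_interaction_for(
                q, factor, scans[cond1], scans[cond2],
                variant=variant, class_alpha=class_alpha))
    return additional, results


def condition_correlations(values: pd.DataFrame,
                           pairing: str = "diet") -> pd.DataFrame:
    """Pearson correlation between paired condition values, per trait.

    ``values`` must have columns ``item`` (sire or marker id), ``trait``,
    ``condition`` and ``value``; ``pairing`` selects HE-vs-LE
    (``"diet"``) or 50-vs-70-week (``"age"``) pairs. The correlation is
    computed on the intersection of items present in both conditions;
    traits with fewer than 3 complete pairs are flagged undefined (NaN).
    """
    if pairing not in FACTOR_PAIRS:
        raise ValueError(f"unknown pairing {pairing!r}")
    c1, c2 = FACTOR_PAIRS[pairing]
    rows = []
    for trait, grp in values.groupby("trait", sort=True):
        wide = grp.pivot_table(index="item", columns="condition",
                               values="value", aggfunc="first")
        if c1 not in wide.columns or c2 not in wide.columns:
            continue
        wide = wide[[c1, c2]].dropna()
        if len(wide) < 3:
            rows.append({"trait": trait, "pairing": pairing, "r": np.nan,
                         "n": len(wide), "defined": False})
            continue
        r = float(np.corrcoef(wide[c1], wide[c2])[0, 1])
        rows.append({"trait": trait, "pairing": pairing, "r": r,
                     "n": len(wide), "defined": True})
    return pd.DataFrame(rows, columns=["trait", "pairing", "r", "n", "defined"])
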