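"""Sequential SNP quality control with an auditable exclusion ledger.

Five filters are applied strictly in order, each computed on the markers
and individuals surviving the previous steps:

1. markers with a pathologically low call rate (< 5 % by default — the
   hallmark of assaying W-chromosome probes in ZZ males);
2. individuals with call rate below threshold;
3. markers with minor-allele frequency below threshold;
4. markers with call rate below threshold;
5. markers deviating from Hardy-Weinberg equilibrium.

The :class:`FilterReport` records per-step exclusion counts and must
reconcile: initial minus the summed exclusions equals the final count,
separately for markers and individuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import GenotypeMatrix, PipelineError

__all__ = ["FilterStep", "FilterReport", "apply_snp_filters", "hwe_chi2", "hwe_exact"]


@dataclass
class FilterStep:
    name: str
    criterion: str
    threshold: float
    n_markers_excluded: int
    n_individuals_excluded: int


@dataclass
class FilterReport:
    """Ordered ledger of the sequential filter steps."""

    initial_markers: int
    initial_individuals: int
    steps: list[FilterStep] = field(default_factory=list)

    @property
    def final_markers(self) -> int:
        return self.initial_markers - sum(s.n_markers_excluded for s in self.steps)

    @property
    def final_individuals(self) -> int:
        return self.initial_individuals - sum(s.n_individuals_excluded for s in self.steps)

    def reconciles(self, final_markers: int, final_individuals: int) -> bool:
        """Check initial − Σ exclusions == final for markers and individuals."""
        return (self.final_markers == final_markers
                and self.final_individuals == final_individuals)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"step": i + 1, "name": s.name, "criterion": s.criterion,
             "threshold": s.threshold,
             "n_markers_excluded": s.n_markers_excluded,
             "n_individuals_excluded": s.n_individuals_excluded}
            for i, s in enumerate(self.steps)
        ]
        return pd.DataFrame(rows)


def hwe_chi2(n_AA: int, n_Aa: int, n_aa: int) -> tuple[float, float]:
    """1-df chi-square goodness-of-fit test for Hardy-Weinberg equilibrium.

    Expected genotype counts are formed at the observed allele frequency.
    A monomorphic sample is in equilibrium by construction and returns
    ``(0.0, 1.0)``.
    """
    counts = np.array([n_AA, n_Aa, n_aa], dtype=float)
    if np.any(counts < 0):
        raise ValueError("genotype counts must be non-negative")
    n = counts.sum()
    if n < 1:
        raise ValueError("need at least one genotyped individual")
    p = (2 * counts[0] + counts[1]) / (2 * n)
    if p in (0.0, 1.0):
        return 0.0, 1.0
    expected = n * np.array([p**2, 2 * p * (1 - p), (1 - p) ** 2])
    stat = float(((counts - expected) ** 2 / expected).sum())
    return stat, float(stats.chi2.sf(stat, df=1))


def hwe_exact(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact Hardy-Weinberg test p-value (sum of probabilities <= observed).

    Conditions on the observed allele counts and enumerates heterozygote
    counts of the same parity; offered as an alternative to the default
    chi-square test for small samples.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    n_a = 2 * n_aa + n_Aa  # minor-allele count
    n_a = min(n_a, 2 * n - n_a)
    if n_a == 0:
        return 1.0
    hets = np.arange(n_a % 2, n_a + 1, 2)
    # log-probabilities of each possible heterozygote count
    from scipy.special import gammaln

    def logp(h):
        hom_minor = (n_a - h) // 2
        hom_major = n - h - hom_minor
        return (gammaln(n + 1) - gammaln(h + 1) - gammaln(hom_minor + 1)
                - gammaln(hom_major + 1) + h * np.log(2)
                + gammaln(n_a + 1) + gammaln(2 * n - n_a + 1) - gammaln(2 * n + 1))

    lp = logp(hets.astype(float))
    prob = np.exp(lp - lp.max())
    prob /= prob.sum()
    # n_Aa always shares the parity of the minor-allele count
    p_obs = prob[hets == n_Aa][0]
    return float(min(1.0, prob[prob <= p_obs * (1 + 1e-12)].sum()))


def _genotype_counts(dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-marker counts of (major hom, het, minor hom) from dosages."""
    n0 = np.nansum(dosages == 0, axis=0)
    n1 = np.nansum(dosages == 1, axis=0)
    n2 = np.nansum(dosages == 2, axis=0)
    return n0, n1, n2


def _hwe_pvalues(dosages: np.ndarray) -> np.ndarray:
    n0, n1, n2 = _genotype_counts(dosages)
    n = n0 + n1 + n2
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (2 * n2 + n1) / (2 * n)
    poly = (n > 0) & (p > 0) & (p < 1)
    pvals = np.ones(dosages.shape[1])
    e0 = n * (1 - p) ** 2
    e1 = n * 2 * p * (1 - p)
    e2 = n * p**2
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = ((n0 - e0) ** 2 / e0 + (n1 - e1) ** 2 / e1 + (n2 - e2) ** 2 / e2)
    pvals[poly] = stats.chi2.sf(stat[poly], df=1)
    return pvals


def apply_snp_filters(
    g: GenotypeMatrix,
    *,
    snp_call_rate_min: float = 0.95,
    ind_call_rate_min: float = 0.95,
    maf_min: float = 0.05,
    hwe_alpha: float = 0.05,
    w_call_rate_min: float = 0.05,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the five sequential filters; return the surviving matrix and ledger.

    A step that fails both an earlier and a later criterion is counted
    only at the earlier step, because each filter sees only the survivors
    of its predecessors. Raises :class:`PipelineError` (with the partial
    report attached as ``exc.report``) if any step empties the data.
    """
    report = FilterReport(initial_markers=g.n_markers,
                          initial_individuals=g.n_sires)
    current = g

    def check_nonempty(stage: str) -> None:
        if current.n_markers == 0 or current.n_sires == 0:
            err = PipelineError(f"no data left after QC step: {stage}")
            err.report = report
            raise err

    # step 1: near-empty markers (W-chromosome pathology)
    keep = current.call_rate_markers() >= w_call_rate_min
    report.steps.append(FilterStep(
        "low_call_markers", "marker call rate", w_call_rate_min,
        int((~keep).sum()), 0))
    current = current.subset(cols=np.flatnonzero(keep))
    check_nonempty("marker call-rate floor")

    # step 2: individual call rate
    keep_ind = current.call_rate_individuals() >= ind_call_rate_min
    report.steps.append(FilterStep(
        "individual_call_rate", "individual call rate", ind_call_rate_min,
        0, int((~keep_ind).sum())))
    current = current.subset(rows=np.flatnonzero(keep_ind))
    check_nonempty("individual call rate")

    # step 3: minor-allele frequency
    keep = current.maf() >= maf_min
    report.steps.append(FilterStep(
        "maf", "minor allele frequency", maf_min, int((~keep).sum()), 0))
    current = current.subset(cols=np.flatnonzero(keep))
    check_nonempty("MAF")

    # step 4: marker call rate
    keep = current.call_rate_markers() >= snp_call_rate_min
    report.steps.append(FilterStep(
        "marker_call_rate", "marker call rate", snp_call_rate_min,
        int((~keep).sum()), 0))
    current = current.subset(cols=np.flatnonzero(keep))
    check_nonempty("marker call rate")

    # step 5: Hardy-Weinberg equilibrium
    keep = _hwe_pvalues(current.dosages) >= hwe_alpha
    report.steps.append(FilterStep(
        "hwe", "HWE chi-square p-value", hwe_alpha, int((~keep).sum()), 0))
    current = current.subset(cols=np.flatnonzero(keep))
    check_nonempty("HWE")

    assert report.reconciles(current.n_markers, current.n_sires)
    return current, report
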