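"""Single-marker mixed-model association scan on sire performances.

Model per SNP and trait::

    Z = 1*mu + X*alpha + E,    V(E) = A*sigma2_g + I*sigma2_e

where ``Z`` holds the per-sire means of adjusted daughter records,
``X`` the sire minor-allele dosages for the SNP, ``A`` the pedigree
additive relationship matrix, and ``alpha`` the allele substitution
effect.

Variance components are estimated once per trait x condition by REML on
the null model (alpha = 0) and then held fixed across all markers, so
the scan is a generalized-least-squares pass through a single
eigendecomposition of ``A`` (the EMMAX strategy). Significance is
assessed against chromosome-wide thresholds calibrated by Monte-Carlo
sampling of the per-chromosome maximum statistic under the null, and
genome-wide thresholds obtained by Bonferroni across chromosomes
(chromosome-wide machinery run at level 0.05 / n_chromosomes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

from .kinship import RelationshipMatrix

__all__ = ["VarianceComponents", "ThresholdSet", "MixedModelScan",
           "fit_null_reml", "scan_snps", "chromosome_threshold",
           "bonferroni_level", "compute_thresholds"]


@dataclass
class VarianceComponents:
    trait: str
    condition: str
    sigma2_g: float
    sigma2_e: float
    loglik: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.sigma2_g < 0 or self.sigma2_e < 0:
            raise ValueError("variance components must be non-negative")


@dataclass
class ThresholdSet:
    """Per-chromosome significance levels on the p-value scale.

    ``chrom_wide`` holds the 1 % chromosome-wide thresholds,
    ``genome_wide`` the same calibration run at level
    ``genome_alpha / n_chromosomes``; ``unknown_group`` (if set) is the
    plain Bonferroni level for markers without a chromosome assignment.
    """

    chrom_wide: dict[str, float] = field(default_factory=dict)
    genome_wide: dict[str, float] = field(default_factory=dict)
    unknown_group: float | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [{"chrom": c, "chrom_wide": self.chrom_wide[c],
                 "genome_wide": self.genome_wide.get(c, np.nan)}
                for c in self.chrom_wide]
        return pd.DataFrame(rows)


def bonferroni_level(alpha: float, m: int) -> float:
    """Bonferroni-corrected per-test level ``alpha / m``."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


class MixedModelScan:
    """Holds one eigendecomposition of A, reused for REML and every marker.

    Parameters
    ----------
    A
        Pedigree relationship matrix over the scanned sires.
    """

    def __init__(self, A: RelationshipMatrix):
        self.ids = list(A.ids)
        self.n = len(self.ids)
        vals, vecs = np.linalg.eigh(A.values)
        # clip tiny negative eigenvalues from finite-precision symmetry
        self.eigvals = np.clip(vals, 0.0, None)
        self.eigvecs = vecs
        self._A = A.values

    # ---------------- REML ----------------

    def _restricted_ll(self, h: float, ystar: np.ndarray, xstar: np.ndarray) -> float:
        """Restricted log-likelihood profiled over the total variance.

        ``h`` is the heritability-like ratio sigma2_g / (sigma2_g +
        sigma2_e); the rotated model has independent residuals with
        variances proportional to ``h * d_i + (1 - h)``.
        """
        v = h * self.eigvals + (1.0 - h)
        if np.any(v <= 0):
            return -np.inf
        w = 1.0 / v
        xtvx = np.sum(w * xstar**2)
        mu = np.sum(w * xstar * ystar) / xtvx
        r = ystar - mu * xstar
        df = self.n - 1
        s2 = np.sum(w * r**2) / df
        if s2 <= 0:
            return -np.inf
        return -0.5 * (df * (np.log(2 * np.pi * s2) + 1)
                       + np.sum(np.log(v)) + np.log(xtvx))

    def fit_null_reml(self, y: np.ndarray, trait: str = "",
                      condition: str = "") -> VarianceComponents:
        """REML variance components of the intercept-only null model.

        Maximizes the restricted likelihood over the variance ratio by
        bounded scalar optimization (the eigendecomposition makes each
        evaluation O(n)); components are clipped at zero. A constant
        phenotype yields both components zero, flagged degenerate.
        """
        y = np.asarray(y, dtype=float)
        if y.shape != (self.n,):
            raise ValueError("phenotype length does not match matrix order")
        if np.ptp(y) == 0:
            return VarianceComponents(trait, condition, 0.0, 0.0,
                                      loglik=np.nan, degenerate=True)
        ystar = self.eigvecs.T @ y
        xstar = self.eigvecs.T @ np.ones(self.n)
        eps = 1e-6
        res = optimize.minimize_scalar(
            lambda h: -self._restricted_ll(h, ystar, xstar),
            bounds=(eps, 1 - eps), method="bounded",
            options={"xatol": 1e-8})
        cands = [(self._restricted_ll(h, ystar, xstar), h)
                 for h in (0.0, float(res.x))]
        ll, h = max(cands)
        if not np.isfinite(ll):
            raise FloatingPointError("non-finite restricted likelihood "
                                     f"(trait={trait!r}, condition={condition!r})")
        v = h * self.eigvals + (1.0 - h)
        w = 1.0 / v
        mu = np.sum(w * xstar * ystar) / np.sum(w * xstar**2)
        s2 = np.sum(w * (ystar - mu * xstar) ** 2) / (self.n - 1)
        return VarianceComponents(trait, condition,
                                  sigma2_g=float(h * s2),
                                  sigma2_e=float((1 - h) * s2),
                                  loglik=float(ll))

    # ---------------- per-marker GLS ----------------

    def _whiten(self, vc: VarianceComponents) -> np.ndarray:
        """Rows of W such that W V W' = I for V = A*sg + I*se.

        A degenerate fit (both components zero, e.g. a constant
        phenotype) falls back to identity covariance so the scan still
        returns exact zeros rather than failing.
        """
        if vc.sigma2_g == 0 and vc.sigma2_e == 0:
            return np.eye(self.n)
        v = vc.sigma2_g * self.eigvals + vc.sigma2_e
        if np.any(v <= 0):
            raise ValueError("covariance matrix is singular")
        return (self.eigvecs / np.sqrt(v)).T

    def scan(self, y: np.ndarray, dosages: np.ndarray,
             markers: pd.DataFrame, vc: VarianceComponents) -> pd.DataFrame:
        """GLS of sire means on dosage for every marker, V held fixed.

        Markers with missing dosages are handled by dropping the affected
        sires and solving against the sub-covariance directly; markers
        monomorphic after drops are flagged (NaN estimates, no test).

        Returns one row per marker: alpha (trait units per minor
        allele), its standard error, Wald z and two-sided normal
        p-value, the MAF among used sires and the sire count.
        """
        y = np.asarray(y, dtype=float)
        G = np.asarray(dosages, dtype=float)
        n, m = G.shape
        if n != self.n or len(markers) != m:
            raise ValueError("dimension mismatch between dosages, y and A")
        alpha = np.full(m, np.nan)
        se = np.full(m, np.nan)
        maf = np.full(m, np.nan)
        n_used = np.zeros(m, dtype=int)
        complete = ~np.isnan(G).any(axis=0)

        # fast path: all sires present -> shared whitening
        W = self._whiten(vc)
        yt = W @ y
        ones_t = W @ np.ones(n)
        idx = np.flatnonzero(complete)
        if idx.size:
            Xt = W @ G[:, idx]
            a = ones_t @ ones_t
            b = ones_t @ Xt
            c = np.einsum("ij,ij->j", Xt, Xt)
            p1 = ones_t @ yt
            q = Xt.T @ yt
            det = a * c - b**2
            poly = det > 1e-10 * a * np.maximum(c, 1e-300)
            with np.errstate(invalid="ignore", divide="ignore"):
                est = (a * q - b * p1) / det
                var = a / det
            alpha[idx[poly]] = est[poly]
            se[idx[poly]] = np.sqrt(var[poly])
            f = G[:, idx].mean(axis=0) / 2
            maf[idx] = np.minimum(f, 1 - f)
            n_used[idx] = n

        # slow path: markers with missing sires, grouped by pattern
        if vc.sigma2_g == 0 and vc.sigma2_e == 0:
            V = np.eye(n)
        else:
            V = vc.sigma2_g * self._A + vc.sigma2_e * np.eye(n)
        incomplete = np.flatnonzero(~complete)
        if incomplete.size:
            patterns: dict[bytes, list[int]] = {}
            miss = np.isnan(G[:, incomplete])
            for k, j in enumerate(incomplete):
                patterns.setdefault(miss[:, k].tobytes(), []).append(j)
            for key, cols in patterns.items():
                keep = ~np.frombuffer(key, dtype=bool)
                nk = int(keep.sum())
                if nk < 3:
                    continue
                ck = cho_factor(V[np.ix_(keep, keep)])
                yk = y[keep]
                for j in cols:
                    x = G[keep, j]
                    f = x.mean() / 2
                    if f in (0.0, 1.0):
                        maf[j] = 0.0
                        n_used[j] = nk
                        continue
                    X = np.column_stack([np.ones(nk), x])
                    VX = cho_solve(ck, X)
                    xtvx = X.T @ VX
                    beta = np.linalg.solve(xtvx, VX.T @ yk)
                    cov = np.linalg.inv(xtvx)
                    alpha[j] = beta[1]
                    se[j] = np.sqrt(cov[1, 1])
                    maf[j] = min(f, 1 - f)
                    n_used[j] = nk

        with np.errstate(invalid="ignore", divide="ignore"):
            z = alpha / se
        pvals = 2 * stats.norm.sf(np.abs(z))
        out = markers[["marker", "chrom", "pos"]].copy().reset_index(drop=True)
        out["maf"] = maf
        out["n_sires"] = n_used
        out["alpha"] = alpha
        out["se"] = se
        out["wald_z"] = z
        out["p"] = pvals
        out["tested"] = np.isfinite(se)
        return out

    # ---------------- threshold calibration ----------------

    def chromosome_threshold(self, dosages: np.ndarray, vc: VarianceComponents,
                             *, level: float = 0.01, n_draws: int = 10_000,
                             seed: int = 0) -> float:
        """Monte-Carlo max-statistic p-value threshold for one chromosome.

        Under the global null the vector of per-marker Wald statistics is
        multivariate normal with correlation equal to the correlation of
        the GLS-whitened, intercept-residualized genotypes. Draws of that
        vector are generated directly as projections of iid normal noise
        onto the whitened genotype columns; the threshold is the
        ``level``-quantile of the per-draw minimum p-value, i.e. a
        per-marker level with family-wise error ``level`` that honours
        the correlation between markers.
        """
        if n_draws < 1.0 / level:
            raise ValueError("n_draws too small for a stable quantile at this level")
        G = np.asarray(dosages, dtype=float)
        if G.shape[1] < 1:
            raise ValueError("need at least one marker on the chromosome")
        G = np.where(np.isnan(G), np.nanmean(G, axis=0), G)
        W = self._whiten(vc)
        Xt = W @ G
        ones_t = W @ np.ones(self.n)
        u = ones_t / np.linalg.norm(ones_t)
        Xt = Xt - np.outer(u, u @ Xt)
        norms = np.linalg.norm(Xt, axis=0)
        keep = norms > 1e-10
        if not keep.any():
            return level
        Xt = Xt[:, keep] / norms[keep]
        rng = np.random.default_rng(seed)
        pmin = np.empty(n_draws)
        chunk = max(1, int(2e7) // self.n)
        done = 0
        while done < n_draws:
            k = min(chunk, n_draws - done)
            Zn = rng.standard_normal((k, self.n))
            T = Zn @ Xt
            pmin[done:done + k] = 2 * stats.norm.sf(np.abs(T).max(axis=1))
            done += k
        return float(np.quantile(pmin, level))


def fit_null_reml(y, A: RelationshipMatrix, trait: str = "",
                  condition: str = "") -> VarianceComponents:
    """Convenience wrapper: REML variance components for one phenotype."""
    return MixedModelScan(A).fit_null_reml(np.asarray(y, float), trait, condition)


def scan_snps(y, genotypes, A: RelationshipMatrix,
              vc: VarianceComponents) -> pd.DataFrame:
    """Convenience wrapper around :meth:`MixedModelScan.scan`."""
    return MixedModelScan(A).scan(np.asarray(y, float), genotypes.dosages,
                                  genotypes.markers, vc)


def chromosome_threshold(genotypes, A: RelationshipMatrix,
                         vc: VarianceComponents, *, level: float = 0.01,
                         n_draws: int = 10_000, seed: int = 0) -> float:
    """Convenience wrapper around :meth:`MixedModelScan.chromosome_threshold`."""
    return MixedModelScan(A).chromosome_threshold(
        genotypes.dosages, vc, level=level, n_draws=n_draws, seed=seed)


def compute_thresholds(scanner: MixedModelScan, genotypes,
                       vc: VarianceComponents, *, chrom_level: float = 0.01,
                       genome_alpha: float = 0.05,
                       n_chromosomes: int | None = None,
                       unknown_chrom: str | None = None,
                       n_draws: int = 10_000, seed: int = 0,
                       method: str = "montecarlo") -> ThresholdSet:
    """Chromosome- and genome-wide thresholds for every chromosome.

    The genome-wide rule follows the published convention: the
    chromosome-wide machinery evaluated at level
    ``genome_alpha / n_chromosomes`` (``n_chromosomes`` defaults to the
    number of chromosome labels actually scanned). Markers on
    ``unknown_chrom``, if given, instead get a plain Bonferroni level
    ``genome_alpha / m_group`` recorded as ``unknown_group``.
    ``method="bonferroni"`` replaces the Monte-Carlo calibration with
    ``level / m`` per chromosome.
    """
    markers = genotypes.markers
    chroms = [c for c in markers["chrom"].unique() if c != unknown_chrom]
    if n_chromosomes is None:
        n_chromosomes = len(chroms)
    # genome-wide significance must imply chromosome-wide significance
    # (the QTL interval is anchored on the chromosome-wide run), so the
    # genome level is capped at the chromosome level; with ~32
    # chromosomes the Bonferroni quotient is far below 1 % anyway
    genome_level = min(bonferroni_level(genome_alpha, n_chromosomes),
                       chrom_level)
    ts = ThresholdSet()
    for i, chrom in enumerate(chroms):
        cols = np.flatnonzero((markers["chrom"] == chrom).to_numpy())
        dos = genotypes.dosages[:, cols]
        if method == "bonferroni":
            ts.chrom_wide[chrom] = bonferroni_level(chrom_level, len(cols))
            ts.genome_wide[chrom] = bonferroni_level(genome_level, len(cols))
        else:
            ts.chrom_wide[chrom] = scanner.chromosome_threshold(
                dos, vc, level=chrom_level, n_draws=n_draws, seed=seed + 2 * i)
            gw = (ts.chrom_wide[chrom] if genome_level == chrom_level
                  else scanner.chromosome_threshold(
                      dos, vc, level=genome_level,
                      n_draws=max(n_draws, int(np.ceil(2.0 / genome_level))),
                      seed=seed + 2 * i + 1))
            # Monte-Carlo noise must not invert the significance hierarchy
            ts.genome_wide[chrom] = min(gw, ts.chrom_wide[chrom])
    if unknown_chrom is not None:
        m_group = int((markers["chrom"] == unknown_chrom).sum())
        if m_group:
            ts.unknown_group = bonferroni_level(genome_alpha, m_group)
            ts.chrom_wide[unknown_chrom] = ts.unknown_group
            ts.genome_wide[unknown_chrom] = ts.unknown_group
    return ts
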