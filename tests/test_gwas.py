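import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import random_pedigree
from layerqtl.data import GenotypeMatrix
from layerqtl.gwas import (MixedModelScan, VarianceComponents, bonferroni_level,
                           compute_thresholds)
from layerqtl.kinship import RelationshipMatrix, build_A


def structured_A(rng, n, family_size=5):
    """Block half-sib relationship matrix (0.25 within families)."""
    n_fam = n // family_size
    A = np.eye(n)
    for f in range(n_fam):
        sl = slice(f * family_size, (f + 1) * family_size)
        block = np.full((family_size, family_size), 0.25)
        np.fill_diagonal(block, 1.0)
        A[sl, sl] = block
    ids = [f"S{i}" for i in range(n)]
    return RelationshipMatrix(ids, A)


def draw_mvn(rng, cov):
    L = np.linalg.cholesky(cov + 1e-10 * np.eye(len(cov)))
    return L @ rng.standard_normal(len(cov))


def dense_gls_oracle(y, x, V):
    """Explicit matrix-inverse GLS of y on [1, x] under covariance V."""
    X = np.column_stack([np.ones(len(y)), x])
    Vi = np.linalg.inv(V)
    C = np.linalg.inv(X.T @ Vi @ X)
    beta = C @ X.T @ Vi @ y
    return beta[1], np.sqrt(C[1, 1])


class TestBonferroni:
    def test_published_denominators(self):
        assert bonferroni_level(0.05, 32) == pytest.approx(0.0015625)
        assert bonferroni_level(0.05, 3681) == pytest.approx(1.3583e-5, rel=1e-3)
        assert bonferroni_level(0.05, 1) == 0.05


class TestNullReml:
    def test_constant_phenotype_is_degenerate(self):
        A = structured_A(np.random.default_rng(0), 40)
        vc = MixedModelScan(A).fit_null_reml(np.full(40, 3.0))
        assert vc.degenerate
        assert vc.sigma2_g == vc.sigma2_e == 0.0

    def test_grid_search_oracle_small_instance(self):
        """Optimum matches a dense grid over the variance ratio."""
        rng = np.random.default_rng(5)
        ped = random_pedigree(rng, n=12)
        A = build_A(ped)
        n = len(A.ids)
        y = draw_mvn(rng, 1.3 * A.values + 0.8 * np.eye(n)) + 5.0

        def restricted_ll(sg, se):
            V = sg * A.values + se * np.eye(n)
            X = np.ones((n, 1))
            Vi = np.linalg.inv(V)
            XtViX = X.T @ Vi @ X
            beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
            r = y - (X @ beta).ravel()
            _, ld = np.linalg.slogdet(V)
            return -0.5 * (ld + np.log(np.linalg.det(XtViX))
                           + r @ Vi @ r + (n - 1) * np.log(2 * np.pi))

        vc = MixedModelScan(A).fit_null_reml(y)
        # dense grid oracle over h = sg/(sg+se), profiling total variance
        hs = np.linspace(1e-4, 1 - 1e-4, 2000)
        best_ll, best_h = -np.inf, None
        for h in hs:
            # profile total variance analytically at each h
            V0 = h * A.values + (1 - h) * np.eye(n)
            Vi = np.linalg.inv(V0)
            X = np.ones((n, 1))
            beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
            r = y - (X @ beta).ravel()
            s2 = (r @ Vi @ r) / (n - 1)
            ll = restricted_ll(h * s2, (1 - h) * s2)
            if ll > best_ll:
                best_ll, best_h = ll, h
        total = vc.sigma2_g + vc.sigma2_e
        assert vc.sigma2_g / total == pytest.approx(best_h, abs=2e-3)
        assert restricted_ll(vc.sigma2_g, vc.sigma2_e) >= best_ll - 1e-6

    def test_parameter_recovery_structured_pedigree(self):
        """Mean REML estimates hit sigma2_g = sigma2_e = 1 within 3 SE."""
        rng = np.random.default_rng(17)
        A = structured_A(rng, 300, family_size=10)
        scanner = MixedModelScan(A)
        cov = A.values + np.eye(300)
        L = np.linalg.cholesky(cov)
        ests = np.array([
            [(vc := scanner.fit_null_reml(L @ rng.standard_normal(300))).sigma2_g,
             vc.sigma2_e]
            for _ in range(20)])
        for k, truth in enumerate([1.0, 1.0]):
            se = ests[:, k].std(ddof=1) / np.sqrt(len(ests))
            assert abs(ests[:, k].mean() - truth) < 3 * se + 1e-9


class TestScan:
    def geno(self, rng, n, m):
        dos = rng.binomial(2, rng.uniform(0.1, 0.5, m), size=(n, m)).astype(float)
        markers = pd.DataFrame({"marker": [f"M{j}" for j in range(m)],
                                "chrom": "1", "pos": np.arange(1, m + 1) * 1000})
        return GenotypeMatrix([f"S{i}" for i in range(n)], dos, markers)

    def test_constant_phenotype_gives_zero_effects(self):
        rng = np.random.default_rng(2)
        A = structured_A(rng, 30)
        g = self.geno(rng, 30, 8)
        scanner = MixedModelScan(A)
        vc = scanner.fit_null_reml(np.full(30, 2.0))
        res = scanner.scan(np.full(30, 2.0), g.dosages, g.markers, vc)
        np.testing.assert_allclose(res.loc[res["tested"], "alpha"], 0, atol=1e-12)

    def test_zero_genetic_variance_reduces_to_ols(self):
        rng = np.random.default_rng(3)
        A = structured_A(rng, 50)
        g = self.geno(rng, 50, 12)
        y = rng.normal(size=50)
        vc = VarianceComponents("t", "ALL", 0.0, 1.0, 0.0)
        res = MixedModelScan(A).scan(y, g.dosages, g.markers, vc)
        for j in range(12):
            x = g.dosages[:, j]
            slope = np.polyfit(x, y, 1)[0]
            assert res["alpha"].iloc[j] == pytest.approx(slope, rel=1e-9)

    def test_matches_dense_gls_oracle_small_instance(self):
        rng = np.random.default_rng(4)
        ped = random_pedigree(rng, n=8, p_parent=0.5)
        A = build_A(ped)
        n = len(A.ids)
        g = self.geno(rng, n, 5)
        y = rng.normal(size=n)
        vc = VarianceComponents("t", "ALL", 0.7, 0.5, 0.0)
        res = MixedModelScan(A).scan(y, g.dosages, g.markers, vc)
        V = 0.7 * A.values + 0.5 * np.eye(n)
        for j in range(5):
            if not res["tested"].iloc[j]:
                continue
            a, se = dense_gls_oracle(y, g.dosages[:, j], V)
            assert res["alpha"].iloc[j] == pytest.approx(a, rel=1e-10)
            assert res["se"].iloc[j] == pytest.approx(se, rel=1e-10)

    def test_missing_dosages_drop_sires_and_match_subset_oracle(self):
        rng = np.random.default_rng(9)
        A = structured_A(rng, 40)
        g = self.geno(rng, 40, 3)
        g.dosages[:5, 1] = np.nan
        y = rng.normal(size=40)
        vc = VarianceComponents("t", "ALL", 0.5, 0.5, 0.0)
        res = MixedModelScan(A).scan(y, g.dosages, g.markers, vc)
        keep = np.ones(40, bool)
        keep[:5] = False
        V = (0.5 * A.values + 0.5 * np.eye(40))[np.ix_(keep, keep)]
        a, se = dense_gls_oracle(y[keep], g.dosages[keep, 1], V)
        assert res["n_sires"].iloc[1] == 35
        assert res["alpha"].iloc[1] == pytest.approx(a, rel=1e-9)
        assert res["se"].iloc[1] == pytest.approx(se, rel=1e-9)

    def test_monomorphic_marker_flagged_not_tested(self):
        rng = np.random.default_rng(10)
        A = structured_A(rng, 30)
        g = self.geno(rng, 30, 2)
        g.dosages[:, 0] = 0.0
        vc = VarianceComponents("t", "ALL", 0.5, 0.5, 0.0)
        res = MixedModelScan(A).scan(rng.normal(size=30), g.dosages,
                                     g.markers, vc)
        assert not res["tested"].iloc[0]
        assert np.isnan(res["p"].iloc[0])


class TestChromosomeThreshold:
    def setup_method(self):
        rng = np.random.default_rng(20)
        self.A = structured_A(rng, 200)
        self.scanner = MixedModelScan(self.A)
        self.vc = VarianceComponents("t", "ALL", 0.5, 0.5, 0.0)
        self.rng = rng

    def test_single_marker_threshold_is_the_level(self):
        dos = self.rng.binomial(2, 0.3, size=(200, 1)).astype(float)
        thr = self.scanner.chromosome_threshold(dos, self.vc, level=0.05,
                                                n_draws=20000, seed=1)
        assert thr == pytest.approx(0.05, abs=0.01)

    def test_independent_markers_approach_sidak(self):
        m = 20
        dos = self.rng.binomial(2, 0.3, size=(200, m)).astype(float)
        thr = self.scanner.chromosome_threshold(dos, self.vc, level=0.05,
                                                n_draws=20000, seed=2)
        sidak = 1 - (1 - 0.05) ** (1 / m)
        # genotype columns are only approximately orthogonal at n = 200
        assert sidak / 2.5 < thr < 0.05

    def test_duplicated_marker_has_no_multiplicity_cost(self):
        x = self.rng.binomial(2, 0.3, size=(200, 1)).astype(float)
        dos = np.repeat(x, 10, axis=1)
        thr = self.scanner.chromosome_threshold(dos, self.vc, level=0.05,
                                                n_draws=20000, seed=3)
        assert thr == pytest.approx(0.05, abs=0.012)

    def test_adding_markers_never_raises_threshold(self):
        dos = self.rng.binomial(2, self.rng.uniform(0.1, 0.5, 30),
                                size=(200, 30)).astype(float)
        thr_small = self.scanner.chromosome_threshold(dos[:, :10], self.vc,
                                                      level=0.05,
                                                      n_draws=20000, seed=4)
        thr_big = self.scanner.chromosome_threshold(dos, self.vc, level=0.05,
                                                    n_draws=20000, seed=4)
        assert thr_big <= thr_small + 0.005

    def test_too_few_draws_rejected(self):
        dos = self.rng.binomial(2, 0.3, size=(200, 3)).astype(float)
        with pytest.raises(ValueError, match="n_draws"):
            self.scanner.chromosome_threshold(dos, self.vc, level=0.01,
                                              n_draws=50, seed=0)

    def test_unknown_group_gets_plain_bonferroni_level(self):
        rng = np.random.default_rng(31)
        m = 20
        dos = rng.binomial(2, 0.3, size=(200, m)).astype(float)
        markers = pd.DataFrame({"marker": [f"M{j}" for j in range(m)],
                                "chrom": ["1"] * 12 + ["unknown"] * 8,
                                "pos": list(range(1, 13)) + list(range(1, 9))})
        g = GenotypeMatrix([f"S{i}" for i in range(200)], dos, markers)
        ts = compute_thresholds(self.scanner, g, self.vc, n_draws=2000,
                                seed=0, unknown_chrom="unknown")
        assert ts.unknown_group == pytest.approx(0.05 / 8)
        assert ts.chrom_wide["unknown"] == ts.unknown_group
        assert "unknown" not in [c for c in ts.chrom_wide if c != "unknown"
                                 and c != "1"]

    def test_bonferroni_fallback_method(self):
        rng = np.random.default_rng(32)
        m = 10
        dos = rng.binomial(2, 0.3, size=(200, m)).astype(float)
        markers = pd.DataFrame({"marker": [f"M{j}" for j in range(m)],
                                "chrom": "1", "pos": range(1, m + 1)})
        g = GenotypeMatrix([f"S{i}" for i in range(200)], dos, markers)
        ts = compute_thresholds(self.scanner, g, self.vc, n_chromosomes=32,
                                method="bonferroni")
        assert ts.chrom_wide["1"] == pytest.approx(0.01 / m)
        assert ts.genome_wide["1"] == pytest.approx(0.05 / 32 / m)

    def test_genome_wide_leq_chromosome_wide(self):
        rng = np.random.default_rng(30)
        m = 25
        dos = rng.binomial(2, rng.uniform(0.1, 0.5, m), size=(200, m)).astype(float)
        markers = pd.DataFrame({"marker": [f"M{j}" for j in range(m)],
                                "chrom": ["1"] * 15 + ["2"] * 10,
                                "pos": list(range(1, 16)) + list(range(1, 11))})
        g = GenotypeMatrix([f"S{i}" for i in range(200)], dos, markers)
        ts = compute_thresholds(self.scanner, g, self.vc, n_draws=4000, seed=1)
        for chrom in ts.chrom_wide:
            assert ts.genome_wide[chrom] <= ts.chrom_wide[chrom]
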