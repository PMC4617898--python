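import numpy as np
import pandas as pd
import pytest
from scipy import stats

from layerqtl.data import GenotypeMatrix, PipelineError
from layerqtl.qc import (FilterReport, FilterStep, apply_snp_filters, hwe_chi2,
                         hwe_exact)


def make_geno(dosages, chrom="1"):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    markers = pd.DataFrame({
        "marker": [f"M{j}" for j in range(m)],
        "chrom": chrom, "pos": np.arange(1, m + 1) * 100,
    })
    return GenotypeMatrix([f"S{i}" for i in range(n)], dosages, markers)


class TestHweChi2:
    def test_exact_equilibrium_proportions(self):
        assert hwe_chi2(25, 50, 25) == (0.0, 1.0)

    def test_monomorphic_is_in_equilibrium(self):
        assert hwe_chi2(100, 0, 0) == (0.0, 1.0)

    def test_arithmetic_oracle(self):
        # p_hat = (2*30+30)/200 = 0.45; chi2 = sum (obs-exp)^2/exp
        n = 100
        p = 0.45
        exp = n * np.array([p**2, 2 * p * (1 - p), (1 - p) ** 2])
        # dosage codes minor-allele count: (hom-major, het, hom-minor)
        obs = np.array([30, 30, 40])
        # careful: p_hat above is the frequency of the allele counted in
        # the third class: (2*40+30)/200 = 0.55 -> fold to 0.45 for class 1
        p1 = (2 * 30 + 30) / 200
        exp = n * np.array([p1**2, 2 * p1 * (1 - p1), (1 - p1) ** 2])
        oracle = float((((obs - exp) ** 2) / exp).sum())
        stat, pval = hwe_chi2(30, 30, 40)
        assert stat == pytest.approx(oracle)
        assert pval == pytest.approx(stats.chi2.sf(oracle, 1))
        assert stat == pytest.approx(15.5, rel=0.01)
        assert pval == pytest.approx(8.2e-5, rel=0.05)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_chi2(-1, 2, 3)

    def test_pvalues_uniform_under_equilibrium(self):
        """Simulated HWE genotypes give (super-)uniform chi-square p-values."""
        rng = np.random.default_rng(7)
        n, m = 400, 5000
        maf = rng.uniform(0.1, 0.5, m)
        pvals = []
        for j in range(m):
            geno = rng.choice(3, size=n, p=[(1 - maf[j]) ** 2,
                                            2 * maf[j] * (1 - maf[j]),
                                            maf[j] ** 2])
            c = np.bincount(geno, minlength=3)
            pvals.append(hwe_chi2(c[0], c[1], c[2])[1])
        ks = stats.kstest(pvals, "uniform", alternative="less")
        # one-sided: p-values may be super-uniform but not anti-conservative
        assert ks.pvalue > 0.01

    def test_exact_test_agrees_with_chi2_in_large_balanced_sample(self):
        p_exact = hwe_exact(250, 480, 270)
        _, p_chi = hwe_chi2(250, 480, 270)
        assert p_exact == pytest.approx(p_chi, abs=0.05)
        assert hwe_exact(100, 0, 0) == 1.0


class TestFilterLedger:
    def test_published_counts_reconcile(self):
        report = FilterReport(initial_markers=580_961, initial_individuals=438)
        for name, markers, inds in [("low_call_markers", 14, 0),
                                    ("individual_call_rate", 0, 0),
                                    ("maf", 260_945, 0),
                                    ("marker_call_rate", 9_041, 0),
                                    ("hwe", 26_318, 0)]:
            report.steps.append(FilterStep(name, "", 0.0, markers, inds))
        assert report.final_markers == 284_643
        assert report.final_individuals == 438
        assert report.reconciles(284_643, 438)

    def test_zero_thresholds_change_nothing(self):
        rng = np.random.default_rng(0)
        g = make_geno(rng.binomial(2, 0.3, size=(20, 15)))
        out, report = apply_snp_filters(
            g, snp_call_rate_min=0, ind_call_rate_min=0, maf_min=0,
            hwe_alpha=0, w_call_rate_min=0)
        assert out.n_markers == g.n_markers
        assert out.n_sires == g.n_sires
        np.testing.assert_array_equal(out.dosages, g.dosages)
        assert all(s.n_markers_excluded == 0 for s in report.steps)

    def test_hand_enumerated_fixture(self):
        """10 markers x 6 sires with designed pathologies, vs hand counts."""
        nan = np.nan
        dos = np.array([
            # columns: 0 empty, 1 ok, 2 low-maf, 3 ok, 4 half-missing,
            # 5 hwe-violating, 6 ok, 7 monomorphic, 8 ok, 9 ok
            [nan, 1, 0, 1, nan, 2, 0, 0, 1, 2],
            [nan, 0, 0, 2, nan, 2, 1, 0, 1, 1],
            [nan, 1, 0, 1, nan, 0, 1, 0, 0, 1],
            [nan, 2, 0, 0, nan, 0, 0, 0, 1, 0],
            [nan, 1, 0, 1, 1.0, 2, 1, 0, 2, 1],
            [nan, 0, 1, 1, 1.0, 0, 2, 0, 1, 1],
        ])
        g = make_geno(dos)
        out, report = apply_snp_filters(
            g, snp_call_rate_min=0.95, ind_call_rate_min=0.5, maf_min=0.10,
            hwe_alpha=0.05, w_call_rate_min=0.05)
        by_name = {s.name: s for s in report.steps}
        # step 1: column 0 fully missing (call rate 0 < 0.05)
        assert by_name["low_call_markers"].n_markers_excluded == 1
        # step 2: no sire below 50% call rate (worst is 8/10 = 0.8)
        assert by_name["individual_call_rate"].n_individuals_excluded == 0
        # step 3: among survivors, col 2 (maf 1/12) and col 7 (maf 0)
        assert by_name["maf"].n_markers_excluded == 2
        # step 4: col 4 (2/6 calls, maf 0.5 so it survived step 3)
        assert by_name["marker_call_rate"].n_markers_excluded == 1
        # step 5: col 5 (2,2,0,0,2,0: all homozygote, het deficit) fails
        assert by_name["hwe"].n_markers_excluded == 1
        assert out.n_markers == 5
        assert report.reconciles(out.n_markers, out.n_sires)

    def test_order_sensitivity_maf_counted_before_call_rate(self):
        """A marker failing both MAF and call rate is charged to MAF."""
        nan = np.nan
        col = np.array([0, 0, 0, 0, nan, nan], dtype=float)  # maf 0, cr 4/6
        ok = np.array([0, 1, 1, 0, 1, 2], dtype=float)
        g = make_geno(np.column_stack([col, ok]))
        _, report = apply_snp_filters(g, maf_min=0.05, snp_call_rate_min=0.95,
                                      ind_call_rate_min=0.0)
        by_name = {s.name: s for s in report.steps}
        assert by_name["maf"].n_markers_excluded == 1
        assert by_name["marker_call_rate"].n_markers_excluded == 0

    def test_idempotence(self):
        """Re-filtering the survivors excludes nothing.

        Holds whenever no individual sits exactly at the call-rate
        boundary, as with array-typical missingness rates.
        """
        rng = np.random.default_rng(5)
        dos = rng.binomial(2, rng.uniform(0.02, 0.5, 200),
                           size=(80, 200)).astype(float)
        dos[rng.random(dos.shape) < 0.005] = np.nan
        once, _ = apply_snp_filters(make_geno(dos))
        twice, report2 = apply_snp_filters(once)
        assert twice.n_markers == once.n_markers
        assert all(s.n_markers_excluded == 0 and s.n_individuals_excluded == 0
                   for s in report2.steps)

    def test_empty_output_raises_with_partial_report(self):
        g = make_geno(np.full((4, 3), np.nan))
        with pytest.raises(PipelineError) as exc:
            apply_snp_filters(g)
        assert exc.value.report.steps[0].n_markers_excluded == 3
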