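import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import norm, pearsonr

from gwarch.liability import (
    CaseControlDesign,
    LogOddsEffect,
    binarize_and_compare,
    downsample_and_compare,
    effective_sample_size,
    estimate_design_scale,
    liability_to_logodds,
    logodds_to_liability,
    rank_inverse_normal,
    rescale_z,
)
from gwarch.synthetic import CohortSpec, make_cohort

import pandas as pd


class TestEffectiveSampleSize:
    def test_zero_sample_size(self):
        assert effective_sample_size(
            CaseControlDesign(M=0, omega=0.5, K=0.5)
        ) == 0

    def test_balanced_median_split_gives_two_over_pi(self):
        n = effective_sample_size(CaseControlDesign(M=1e5, omega=0.5, K=0.5))
        assert np.isclose(n, 1e5 * 2 / np.pi, rtol=1e-12)
        assert round(n) == 63662

    def test_ten_percent_prevalence_value(self):
        n = effective_sample_size(CaseControlDesign(M=1e5, omega=0.5, K=0.1))
        # scalar evaluation: T = 1.28155, phi(T) = 0.17550
        assert abs(n - 95061) < 5

    def test_case_fraction_half_maximizes_power(self):
        for k in (0.05, 0.2, 0.5):
            mid = effective_sample_size(CaseControlDesign(1e5, 0.5, k))
            lo = effective_sample_size(CaseControlDesign(1e5, 0.45, k))
            hi = effective_sample_size(CaseControlDesign(1e5, 0.55, k))
            assert mid >= lo and mid >= hi

    def test_invalid_prevalence_rejected(self):
        with pytest.raises(ValueError):
            CaseControlDesign(M=100, omega=0.5, K=0.0)


class TestRescaleZ:
    def test_identity_halving_and_zero(self):
        assert rescale_z(3.0, 100, 100) == 3.0
        assert np.isclose(rescale_z(4.0, 100, 25), 2.0)
        assert rescale_z(0.0, 100, 10) == 0.0


class TestLogOddsConversion:
    def test_zero_effect_maps_to_zero(self):
        design = CaseControlDesign(M=1e4, omega=0.3, K=0.2)
        beta, _ = logodds_to_liability(
            LogOddsEffect(zeta=0.0, se=0.1, p=0.2), design
        )
        assert beta == 0.0

    def test_median_prevalence_factor(self):
        design = CaseControlDesign(M=1e4, omega=0.5, K=0.5)
        beta, se = logodds_to_liability(
            LogOddsEffect(zeta=1.0, se=0.5, p=0.2), design
        )
        factor = 0.25 / norm.pdf(0.0)
        assert np.isclose(beta, factor) and np.isclose(se, 0.5 * factor)
        assert np.isclose(factor, 0.62666, atol=1e-5)

    def test_roundtrip_to_machine_precision(self):
        design = CaseControlDesign(M=1e4, omega=0.4, K=0.07)
        beta, se = logodds_to_liability(
            LogOddsEffect(zeta=0.31, se=0.04, p=0.1), design
        )
        zeta, se2 = liability_to_logodds(beta, se, design)
        assert np.isclose(zeta, 0.31, rtol=1e-14)
        assert np.isclose(se2, 0.04, rtol=1e-14)


class TestEstimateDesignScale:
    def test_constructed_inverse(self):
        se = np.sqrt(1.0 / (50_000 * 2 * 0.25 * 0.75))
        df = pd.DataFrame({"maf": [0.25], "se": [se]})
        assert np.isclose(estimate_design_scale(df), 50_000)

    def test_exact_model_recovery_at_every_snp(self):
        rng = np.random.default_rng(0)
        truth = 123_456.0
        p = rng.uniform(0.01, 0.5, 200)
        df = pd.DataFrame(
            {"maf": p, "se": np.sqrt(1.0 / (2 * truth * p * (1 - p)))}
        )
        assert np.isclose(estimate_design_scale(df), truth, rtol=1e-12)

    def test_robust_to_multiplicative_noise(self):
        truth = 80_000.0
        errs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            p = rng.uniform(0.01, 0.5, 500)
            se = np.sqrt(1.0 / (2 * truth * p * (1 - p)))
            se *= 1.0 + 0.1 * rng.standard_normal(500)
            est = estimate_design_scale(pd.DataFrame({"maf": p, "se": se}))
            errs.append(abs(est / truth - 1.0))
        assert np.median(errs) < 0.25

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            estimate_design_scale(pd.DataFrame({"maf": [], "se": []}))


class TestRankInverseNormal:
    def test_moments_and_correlation_for_normal_input(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(10_000)
        y = rank_inverse_normal(x)
        assert abs(y.mean()) < 0.05
        assert abs(y.std() - 1.0) < 0.05
        assert pearsonr(x, y)[0] > 0.99

    @given(
        st.lists(
            st.integers(-1000, 1000), min_size=5, max_size=60, unique=True
        )
    )
    def test_invariant_under_monotone_transform(self, values):
        x = np.array(values, dtype=float) / 7.0
        assert np.allclose(
            rank_inverse_normal(x), rank_inverse_normal(np.exp(x / 50.0))
        )

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            rank_inverse_normal([1.0, 1.0, 1.0])


@pytest.fixture(scope="module")
def cohort():
    return make_cohort(
        CohortSpec(n_individuals=30_000, n_variants=200, heritability=0.4,
                   seed=1)
    )


class TestBinarizeAndCompare:
    def test_median_split_slope_matches_liability_prediction(self, cohort):
        res = binarize_and_compare(cohort, 0.5, "upper", seed=2, n_boot=100)
        assert np.isclose(res.predicted_slope, np.sqrt(2 / np.pi), rtol=1e-12)
        assert abs(res.slope - res.predicted_slope) < 3 * res.se_boot

    def test_tail_symmetry_for_symmetric_phenotype(self, cohort):
        """Lower-tail cases flip the association sign; the deflation
        magnitude must match the upper tail."""
        up = binarize_and_compare(cohort, 0.2, "upper", seed=3, n_boot=100)
        lo = binarize_and_compare(cohort, 0.2, "lower", seed=3, n_boot=100)
        assert lo.slope < 0 < up.slope
        assert abs(up.slope - abs(lo.slope)) < 3 * np.hypot(
            up.se_boot, lo.se_boot
        )

    def test_downsampling_reproduces_binarized_slope(self, cohort):
        res_b = binarize_and_compare(cohort, 0.2, "upper", seed=4, n_boot=100)
        res_d = downsample_and_compare(
            cohort, int(round(res_b.n_prime)), seed=4, n_boot=100
        )
        assert np.isclose(res_d.predicted_slope, res_b.predicted_slope,
                          atol=1e-4)
        assert abs(res_b.slope - res_d.slope) < 3 * np.hypot(
            res_b.se_boot, res_d.se_boot
        )

    def test_large_effects_deviate_under_binarization_only(self, cohort):
        """The liability N' relies on small effects; Eq.-style downsampling
        does not, so only binarization bends the largest-effect decile."""
        res_b = binarize_and_compare(cohort, 0.05, "upper", seed=5, n_boot=50)
        res_d = downsample_and_compare(
            cohort, int(round(res_b.n_prime)), seed=5, n_boot=50
        )
        top = np.abs(cohort.beta) >= np.quantile(np.abs(cohort.beta), 0.9)

        def signed_resid(res):
            return (
                res.z_after - res.predicted_slope * res.z_before
            ) * np.sign(res.z_before)

        rb, rd = signed_resid(res_b), signed_resid(res_d)
        assert rb[top].mean() < rd[top].mean() - 0.05
        assert rb[top].mean() < rb[~top].mean() - 0.05

    def test_insufficient_cases_rejected(self, cohort):
        with pytest.raises(ValueError):
            binarize_and_compare(cohort, 1e-4, "upper")
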