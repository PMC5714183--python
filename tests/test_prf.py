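"""Closed-form and quadrature checks of the PRF/gBGC expectations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad as scipy_quad

from gbgcdfe.models import DFEModel, MutationClass
from gbgcdfe.prf import (
    QuadratureConfig,
    combined_sfs,
    expected_class_sfs,
    expected_divergence,
    fixation_rate_ratio,
    fold_sfs,
    sfs_integrand,
    true_alpha,
    true_omega_a,
)


class TestFixationRateRatio:
    def test_neutral_limit_is_one(self):
        assert fixation_rate_ratio(0.0) == 1.0

    def test_direct_value(self):
        # 2 / (1 - e^-2)
        assert fixation_rate_ratio(2.0) == pytest.approx(2.3130352855, abs=1e-8)

    def test_negative_value(self):
        # u(-2) = 2 / (e^2 - 1)
        assert fixation_rate_ratio(-2.0) == pytest.approx(
            2.0 / (np.e**2 - 1.0), rel=1e-12
        )

    @given(st.floats(min_value=-50, max_value=50))
    @settings(deadline=None, max_examples=100)
    def test_reflection_identity(self, gamma):
        """u(g) - u(-g) = g, an algebraic identity of the fixation ratio."""
        diff = fixation_rate_ratio(gamma) - fixation_rate_ratio(-gamma)
        assert diff == pytest.approx(gamma, rel=1e-9, abs=1e-9)

    @pytest.mark.parametrize("gamma", [-1e4, -2000.0, 2000.0, 1e4])
    def test_extreme_arguments_are_stable(self, gamma):
        with np.errstate(over="raise"):
            v = fixation_rate_ratio(gamma)
        assert np.isfinite(v)
        if gamma > 0:
            assert v == pytest.approx(gamma, rel=1e-12)
        else:
            assert 0 <= v < 1e-300 or v < 1e-12

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            fixation_rate_ratio(np.nan)


class TestSfsIntegrand:
    def test_neutral_limit_formula(self):
        # gamma=0, n=2, i=1, x=0.5: (1/x) C(2,1) x (1-x) = 1
        assert sfs_integrand(0.0, 0.5, 1, 2) == pytest.approx(1.0)

    def test_integral_is_one_over_i(self):
        v, _ = scipy_quad(lambda x: sfs_integrand(0.0, x, 3, 10), 0, 1)
        assert v == pytest.approx(1.0 / 3.0, rel=1e-8)

    def test_strongly_deleterious_no_overflow(self):
        with np.errstate(over="raise"):
            v = sfs_integrand(-2000.0, 0.9, 5, 20)
        assert np.isfinite(v)
        # high-precision oracle via mpmath-free log-space computation
        from scipy.stats import binom

        g, x = -2000.0, 0.9
        ratio = (np.exp(g) - np.exp(g * x)) / np.expm1(g)
        expect = ratio / (x * (1 - x)) * binom.pmf(5, 20, x)
        assert v == pytest.approx(expect, rel=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            sfs_integrand(0.0, 1.5, 1, 10)
        with pytest.raises(ValueError):
            sfs_integrand(0.0, 0.5, 10, 10)


class TestExpectedClassSfs:
    def test_neutral_spectrum_is_theta_over_i(self, table_context, neutral_dfe):
        ctx = table_context(B=0.0)
        sfs = expected_class_sfs(neutral_dfe, ctx, MutationClass.WWSS)
        i = np.arange(1, ctx.sample_size)
        np.testing.assert_allclose(sfs.entries, ctx.theta / i, rtol=1e-6)

    def test_class_weights(self, table_context, neutral_dfe):
        ctx = table_context(B=0.0)
        sw = expected_class_sfs(neutral_dfe, ctx, MutationClass.SW)
        i = np.arange(1, ctx.sample_size)
        np.testing.assert_allclose(
            sw.entries, 0.472 * 2.0 * ctx.theta / i, rtol=1e-6
        )

    def test_combined_is_sum_of_classes(self, table_context, case_dfes):
        ctx = table_context(B=3.0)
        dfe = case_dfes["case1"]
        total = combined_sfs(dfe, ctx)
        parts = [
            expected_class_sfs(dfe, ctx, c)
            for c in (MutationClass.WWSS, MutationClass.WS, MutationClass.SW)
        ]
        np.testing.assert_allclose(
            total.entries, sum(p.entries for p in parts), rtol=1e-12
        )
        assert np.all(total.entries >= 0)

    def test_combined_neutral_singleton_value(self, table_context, neutral_dfe):
        # B=0: (1 + (1-p) + p*kappa) theta = 2.472 * 0.01
        ctx = table_context(B=0.0)
        total = combined_sfs(neutral_dfe, ctx)
        assert total.entries[0] == pytest.approx(0.02472, rel=1e-6)

    def test_quadrature_refinement(self, table_context):
        """Doubling both grids moves the selected spectrum by < 1e-5 relative."""
        ctx = table_context(B=0.0)
        dfe = DFEModel(shape_beta=0.3, mean_gamma=-200.0)
        coarse = expected_class_sfs(
            dfe, ctx, MutationClass.WWSS, QuadratureConfig(256, 256)
        )
        fine = expected_class_sfs(
            dfe, ctx, MutationClass.WWSS, QuadratureConfig(512, 512)
        )
        np.testing.assert_allclose(coarse.entries, fine.entries, rtol=1e-5)

    def test_matches_brute_force_double_quadrature(self, table_context):
        """Heavy-tailed DFE spectrum agrees with a 10x finer independent grid."""
        ctx = table_context(B=0.0)
        dfe = DFEModel(shape_beta=0.3, mean_gamma=-200.0)
        got = expected_class_sfs(
            dfe, ctx, MutationClass.WWSS, QuadratureConfig(256, 256)
        )
        oracle = expected_class_sfs(
            dfe, ctx, MutationClass.WWSS, QuadratureConfig(2560, 2560)
        )
        np.testing.assert_allclose(got.entries, oracle.entries, rtol=1e-4)


class TestFoldSfs:
    def test_neutral_fold_n4(self):
        from gbgcdfe.models import ClassSFS

        theta = 0.02
        sfs = ClassSFS(
            cls=MutationClass.WWSS,
            entries=theta / np.arange(1, 4),
            sample_size=4,
        )
        folded = fold_sfs(sfs)
        np.testing.assert_allclose(
            folded.entries, [theta * (1 + 1 / 3), theta / 2], rtol=1e-12
        )

    def test_mass_conservation(self, table_context, case_dfes):
        ctx = table_context(B=5.0)
        sfs = combined_sfs(case_dfes["case3"], ctx)
        assert fold_sfs(sfs).entries.sum() == pytest.approx(
            sfs.entries.sum(), rel=1e-12
        )

    def test_double_fold_rejected(self, table_context, neutral_dfe):
        ctx = table_context()
        folded = fold_sfs(expected_class_sfs(neutral_dfe, ctx, MutationClass.WWSS))
        with pytest.raises(ValueError):
            fold_sfs(folded)


class TestExpectedDivergence:
    def test_neutral_total(self, table_context, neutral_dfe):
        ctx = table_context(B=0.0)
        d = expected_divergence(neutral_dfe, ctx, t_theta=1.0)
        assert d.k_total == pytest.approx(1.0 + 0.528 + 0.944, rel=1e-9)

    def test_gbgc_shifts(self, table_context, neutral_dfe):
        ctx = table_context(B=2.0)
        d = expected_divergence(neutral_dfe, ctx, t_theta=1.0)
        assert d.k_ws / (1 - 0.472) == pytest.approx(2.3130, abs=1e-4)
        assert d.k_sw / (0.472 * 2.0) == pytest.approx(0.3130, abs=1e-4)

    def test_total_is_sum(self, table_context, case_dfes):
        ctx = table_context(B=5.0)
        d = expected_divergence(case_dfes["case2"], ctx, t_theta=1.0)
        assert d.k_total == pytest.approx(d.k_wwss + d.k_ws + d.k_sw, rel=1e-9)

    def test_gbgc_drives_extra_fixation_at_high_b(self, table_context, case_dfes):
        """Strong gBGC inflates total divergence of the case-1 DFE.

        The response is not monotone from B=0: with kappa=2 the S->W
        mutational input (p kappa theta = 0.944 theta) outweighs the W->S
        input (0.528 theta), so weak gBGC first depresses the total before
        the accelerating W->S fixation takes over.
        """
        totals = {
            B: expected_divergence(
                case_dfes["case1"], table_context(B=B), t_theta=1.0
            ).k_total
            for B in (0.0, 1.0, 3.0, 5.0, 10.0)
        }
        assert totals[1.0] < totals[0.0]  # initial dip: d/dB < 0 at B=0
        assert totals[1.0] < totals[3.0] < totals[5.0] < totals[10.0]
        assert totals[10.0] > totals[0.0]


class TestTrueRates:
    def test_no_beneficial_mass_means_zero_alpha(self, table_context, case_dfes):
        for B in (0.0, 10.0):
            assert true_alpha(case_dfes["case1"], table_context(B=B)) == 0.0

    def test_wwss_closed_form(self, table_context, case_dfes):
        # omega_a(WWSS) = x * u(gamma_b)
        ctx = table_context(B=5.0)
        expect = 0.03 * fixation_rate_ratio(10.0)
        assert true_omega_a(case_dfes["case3"], ctx, "WWSS") == pytest.approx(
            expect, abs=1e-6
        )
        assert expect == pytest.approx(0.30001, abs=1e-5)

    @pytest.mark.parametrize("B", [0.0, 1.0, 3.0, 5.0, 10.0])
    def test_wwss_rates_invariant_in_B(self, table_context, case_dfes, B):
        dfe = case_dfes["case2"]
        assert true_alpha(dfe, table_context(B=B), "WWSS") == pytest.approx(
            true_alpha(dfe, table_context(B=0.0), "WWSS"), abs=1e-6
        )
        assert true_omega_a(dfe, table_context(B=B), "WWSS") == pytest.approx(
            true_omega_a(dfe, table_context(B=0.0), "WWSS"), abs=1e-6
        )

    def test_case3_reference_values(self, table_context, case_dfes):
        dfe = case_dfes["case3"]
        assert true_alpha(dfe, table_context(B=0.0), "WWSS") == pytest.approx(
            0.4442, abs=5e-5
        )
        assert true_alpha(dfe, table_context(B=10.0), "ALL") == pytest.approx(
            0.1801, abs=5e-5
        )
        assert true_omega_a(dfe, table_context(B=5.0), "ALL") == pytest.approx(
            0.1843, abs=5e-5
        )

    def test_case2_reference_values(self, table_context, case_dfes):
        dfe = case_dfes["case2"]
        assert true_alpha(dfe, table_context(B=0.0), "WWSS") == pytest.approx(
            0.1588, abs=5e-5
        )
        assert true_omega_a(dfe, table_context(B=5.0), "ALL") == pytest.approx(
            0.0104, abs=5e-5
        )

    def test_invalid_restriction_rejected(self, table_context, case_dfes):
        with pytest.raises(ValueError):
            true_alpha(case_dfes["case2"], table_context(), "WS")
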