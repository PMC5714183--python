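"""Demography and DFE fitting, alpha/omega, Nes bins, bootstrap."""

import numpy as np
import pytest
from scipy import special, stats

from gbgcdfe.inference import (
    alpha_from_dfe,
    bootstrap_by_gene,
    dfe_mass_in_bins,
    fit_gamma_dfe,
    fit_two_epoch,
    omega_a_from_dfe,
)
from gbgcdfe.models import ClassSFS, DFEModel, MutationClass, TwoEpochDemography
from gbgcdfe.wright_fisher import WrightFisherEngine


def _engine_sfs(engine, gamma, demog, scale, n_sites):
    n2, gens = engine.discretize(demog)
    v = engine.folded_sfs(gamma, n2, gens) * scale * n_sites
    return ClassSFS(
        cls=MutationClass.COMBINED,
        entries=v,
        sample_size=engine.sample_size,
        folded=True,
        site_count=n_sites,
    )


class TestFitTwoEpoch:
    def test_constant_size_recovered(self, small_engine):
        theta = 0.01
        demog = TwoEpochDemography(size_ratio=1.0, change_time=0.0)
        sfs = _engine_sfs(small_engine, 0.0, demog, theta, 1e6)
        fit = fit_two_epoch(sfs, engine=small_engine)
        assert 0.95 <= fit.demography.size_ratio <= 1.05

    def test_expansion_recovered(self, small_engine):
        demog = TwoEpochDemography(size_ratio=2.0, change_time=0.25)
        sfs = _engine_sfs(small_engine, 0.0, demog, 0.01, 1e6)
        fit = fit_two_epoch(sfs, engine=small_engine)
        assert fit.demography.size_ratio == pytest.approx(2.0, rel=0.05)
        assert fit.demography.change_time == pytest.approx(0.25, rel=0.05)

    def test_two_epoch_never_worse_than_constant(self, small_engine):
        """The constant-size model is nested in the two-epoch search space."""
        demog = TwoEpochDemography(size_ratio=2.0, change_time=0.25)
        sfs = _engine_sfs(small_engine, 0.0, demog, 0.01, 1e6)
        fit = fit_two_epoch(sfs, engine=small_engine)
        const = small_engine.folded_sfs(0.0)
        lam = (sfs.entries.sum() / const.sum()) * const
        const_ll = float(np.sum(sfs.entries * np.log(lam) - lam))
        assert fit.log_likelihood >= const_ll

    def test_rejects_unfolded(self, small_engine):
        sfs = ClassSFS(
            cls=MutationClass.COMBINED,
            entries=np.ones(19),
            sample_size=20,
            folded=False,
        )
        with pytest.raises(ValueError):
            fit_two_epoch(sfs, engine=small_engine)


@pytest.fixture(scope="module")
def generated(small_engine):
    """Noise-free engine-generated neutral + selected data, known truth."""
    truth = DFEModel(shape_beta=0.3, mean_gamma=-80.0)
    demog = TwoEpochDemography(size_ratio=1.5, change_time=0.2)
    theta, n_sites = 0.008, 5e6
    neutral = _engine_sfs(small_engine, 0.0, demog, theta, n_sites)
    n2, gens = small_engine.discretize(demog)
    from gbgcdfe.inference import _GAMMA_EDGES, _GAMMA_MIDS

    wts = np.diff(
        stats.gamma.cdf(
            _GAMMA_EDGES, a=truth.shape_beta, scale=truth.gamma_scale
        )
    )
    sel = sum(
        w * small_engine.folded_sfs(-m, n2, gens)
        for m, w in zip(_GAMMA_MIDS, wts)
    )
    selected = ClassSFS(
        cls=MutationClass.COMBINED,
        entries=sel * theta * n_sites,
        sample_size=small_engine.sample_size,
        folded=True,
        site_count=n_sites,
    )
    return truth, neutral, selected


class TestFitGammaDfe:
    def test_parameters_recovered_noise_free(self, small_engine, generated):
        truth, neutral, selected = generated
        demog_fit = fit_two_epoch(neutral, engine=small_engine)
        dfe_fit = fit_gamma_dfe(selected, demog_fit, engine=small_engine)
        assert dfe_fit.dfe.shape_beta == pytest.approx(truth.shape_beta, rel=0.05)
        assert dfe_fit.dfe.mean_gamma == pytest.approx(truth.mean_gamma, rel=0.10)

    def test_likelihood_at_truth_near_optimum(self, small_engine, generated):
        """On noise-free data the fitted optimum cannot beat the generating
        parameters by more than a hair."""
        truth, neutral, selected = generated
        demog_fit = fit_two_epoch(neutral, engine=small_engine)
        dfe_fit = fit_gamma_dfe(selected, demog_fit, engine=small_engine)
        single = fit_gamma_dfe(
            selected,
            demog_fit,
            engine=small_engine,
            starts=[(truth.shape_beta, truth.mean_abs_gamma)],
        )
        assert dfe_fit.log_likelihood - single.log_likelihood < 1e-3

    def test_poisson_sampled_recovery(self, small_engine):
        """Sampled counts at 5e6 sites recover beta within +-0.05."""
        truth = DFEModel(shape_beta=0.3, mean_gamma=-200.0)
        demog = TwoEpochDemography(size_ratio=1.0, change_time=0.0)
        theta, n_sites = 0.01, 5e6
        neutral = _engine_sfs(small_engine, 0.0, demog, theta, n_sites)
        from gbgcdfe.inference import _GAMMA_EDGES, _GAMMA_MIDS

        wts = np.diff(
            stats.gamma.cdf(
                _GAMMA_EDGES, a=truth.shape_beta, scale=truth.gamma_scale
            )
        )
        sel = sum(
            w * small_engine.folded_sfs(-m) for m, w in zip(_GAMMA_MIDS, wts)
        )
        rng = np.random.default_rng(20170213)
        selected = ClassSFS(
            cls=MutationClass.COMBINED,
            entries=rng.poisson(sel * theta * n_sites).astype(float),
            sample_size=small_engine.sample_size,
            folded=True,
            site_count=n_sites,
        )
        neutral = ClassSFS(
            cls=neutral.cls,
            entries=rng.poisson(neutral.entries).astype(float),
            sample_size=neutral.sample_size,
            folded=True,
            site_count=neutral.site_count,
        )
        demog_fit = fit_two_epoch(neutral, engine=small_engine)
        dfe_fit = fit_gamma_dfe(selected, demog_fit, engine=small_engine)
        assert abs(dfe_fit.dfe.shape_beta - 0.3) < 0.05


class TestAlphaOmega:
    def test_neutral_dfe_equal_divergence_gives_zero(self):
        dfe = DFEModel(shape_beta=1.0, mean_gamma=0.0)
        assert alpha_from_dfe(dfe, k0=1.0, k4=1.0) == pytest.approx(0.0)
        assert omega_a_from_dfe(dfe, k0=1.0, k4=1.0) == pytest.approx(0.0)

    def test_strong_selection_limit(self):
        dfe = DFEModel(shape_beta=2.0, mean_gamma=-1e6)
        assert alpha_from_dfe(dfe, k0=0.5, k4=1.0) == pytest.approx(1.0, abs=1e-6)

    def test_omega_alpha_identity(self, case_dfes):
        """omega_a = alpha * k0/k4 follows from the two defining equations."""
        dfe = case_dfes["case1"]
        for k0, k4 in [(0.8, 1.0), (1.3, 0.7)]:
            a = alpha_from_dfe(dfe, k0, k4)
            w = omega_a_from_dfe(dfe, k0, k4)
            assert w == pytest.approx(a * k0 / k4, rel=1e-9)

    def test_zero_k0_raises(self):
        dfe = DFEModel(shape_beta=1.0, mean_gamma=0.0)
        with pytest.raises(ZeroDivisionError):
            alpha_from_dfe(dfe, k0=0.0, k4=1.0)


class TestNesBins:
    def test_weak_point_mass_is_nearly_neutral(self):
        dfe = DFEModel(shape_beta=1.0, mean_gamma=0.0)
        bins = dfe_mass_in_bins(dfe)
        assert bins.nearly_neutral == 1.0

    def test_incomplete_gamma_oracle(self):
        """Bin masses equal regularized incomplete gamma values."""
        dfe = DFEModel(shape_beta=0.2, mean_gamma=-40.0)
        bins = dfe_mass_in_bins(dfe, edges=(1.0, 10.0), nes_scale=1.0)
        scale = 40.0 / 0.2
        p1 = special.gammainc(0.2, 1.0 / scale)
        p10 = special.gammainc(0.2, 10.0 / scale)
        assert bins.nearly_neutral == pytest.approx(p1, rel=1e-10)
        assert bins.intermediate == pytest.approx(p10 - p1, rel=1e-10)
        assert bins.strong == pytest.approx(1 - p10, rel=1e-10)

    def test_sum_to_one(self, case_dfes):
        for dfe in case_dfes.values():
            b = dfe_mass_in_bins(dfe)
            assert b.nearly_neutral + b.intermediate + b.strong == pytest.approx(1.0)

    def test_scale_switch_moves_mass(self):
        dfe = DFEModel(shape_beta=0.3, mean_gamma=-50.0)
        on_nes = dfe_mass_in_bins(dfe, nes_scale=4.0)
        on_gamma = dfe_mass_in_bins(dfe, nes_scale=1.0)
        assert on_nes.nearly_neutral > on_gamma.nearly_neutral


class TestBootstrap:
    def test_identical_genes_zero_width(self):
        genes = [1.0] * 10
        lo, hi = bootstrap_by_gene(genes, statistic=np.mean, reps=50, seed=1)
        assert lo == hi == 1.0

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(3)
        genes = list(rng.normal(size=30))
        a = bootstrap_by_gene(genes, np.mean, reps=200, seed=11)
        b = bootstrap_by_gene(genes, np.mean, reps=200, seed=11)
        assert a == b
        c = bootstrap_by_gene(genes, np.mean, reps=200, seed=12)
        assert a != c

    def test_coverage_on_normal_mean(self):
        """95% percentile CI covers the true mean ~95% of the time."""
        rng = np.random.default_rng(42)
        hits = 0
        trials = 1000
        for t in range(trials):
            genes = list(rng.normal(size=40))
            lo, hi = bootstrap_by_gene(genes, np.mean, reps=200, seed=t)
            hits += lo <= 0.0 <= hi
        assert 0.92 <= hits / trials <= 0.98

    def test_degenerate_replicates_skipped(self, caplog):
        genes = [0.0] * 5 + [1.0]

        def frac_positive(sample):
            s = sum(sample)
            if s == 0:
                raise ZeroDivisionError("no sites")
            return s / len(sample)

        lo, hi = bootstrap_by_gene(genes, frac_positive, reps=100, seed=5)
        assert 0 < lo <= hi


class TestWwssSelfConsistency:
    """On WWSS-only data (immune to gBGC) the pipeline recovers the true alpha."""

    @pytest.mark.parametrize(
        "beta,mean_gamma,x,gamma_b",
        [(0.3, -2000.0, 0.005, 3.0), (0.2, -40.0, 0.03, 10.0)],
    )
    def test_alpha_matches_analytic_truth(self, beta, mean_gamma, x, gamma_b):
        from gbgcdfe.models import GBGCContext
        from gbgcdfe.prf import (
            expected_class_sfs,
            expected_divergence,
            fold_sfs,
            true_alpha,
        )

        ctx = GBGCContext(
            B=0.0, kappa=2.0, gc_content=0.472, theta=0.01, sample_size=50
        )
        full = DFEModel(
            shape_beta=beta,
            mean_gamma=mean_gamma,
            beneficial_fraction=x,
            beneficial_gamma=gamma_b,
        )
        deleterious = DFEModel(shape_beta=beta, mean_gamma=mean_gamma)
        neutral_dfe = DFEModel(shape_beta=1.0, mean_gamma=0.0)
        n_sites = 5e6
        neutral = fold_sfs(
            expected_class_sfs(neutral_dfe, ctx, MutationClass.WWSS)
        ).scaled(n_sites)
        raw = fold_sfs(expected_class_sfs(deleterious, ctx, MutationClass.WWSS))
        selected = ClassSFS(
            cls=raw.cls,
            entries=raw.entries * (1 - x) * n_sites,
            sample_size=50,
            folded=True,
            site_count=n_sites,
        )
        engine = WrightFisherEngine(sample_size=50)
        demog_fit = fit_two_epoch(neutral, engine=engine)
        dfe_fit = fit_gamma_dfe(selected, demog_fit, engine=engine)
        k0 = expected_divergence(full, ctx, 1.0).k_wwss
        k4 = expected_divergence(neutral_dfe, ctx, 1.0).k_wwss
        alpha_hat = alpha_from_dfe(dfe_fit.dfe, k0, k4)
        assert alpha_hat == pytest.approx(
            true_alpha(full, ctx, "WWSS"), abs=0.01
        )
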