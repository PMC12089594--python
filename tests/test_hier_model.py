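import numpy as np
import pytest

from vaxstab.core_io import Container, StabilityDataset, StabilityRecord
from vaxstab.hier_model import (
    McmcConfig,
    ModelSpec,
    NEW_BATCH,
    PosteriorDraws,
    PredictionTarget,
    PriorConfig,
    closed_form_posterior_oracle,
    estimate_shelf_life,
    fit_gibbs,
    load_draws,
    posterior_summary,
    predictive_interval,
    save_draws,
)
from vaxstab.synthetic_data import GeneratorConfig, sample_true_parameters

from .conftest import single_group_dataset


def ols_line(x, y):
    return np.polynomial.polynomial.polyfit(np.asarray(x), np.asarray(y), 1)


class TestClosedFormOracle:
    def test_vague_prior_equals_ols(self):
        x, y, _ = single_group_dataset(seed=1)
        post = closed_form_posterior_oracle(x, y)
        np.testing.assert_allclose(post.coef_mean, ols_line(x, y), rtol=1e-4)

    def test_consistency_at_large_n(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 36, size=10_000)
        y = 100.0 - 0.5 * x + rng.normal(0, 2, size=10_000)
        post = closed_form_posterior_oracle(x, y)
        assert post.coef_mean[1] == pytest.approx(-0.5, abs=0.01)
        assert post.sigma2_mean == pytest.approx(4.0, rel=0.05)

    def test_dogmatic_prior_returns_prior_mean(self):
        x, y, _ = single_group_dataset(seed=2)
        priors = PriorConfig(mean_prior_variance=1e-10)
        post = closed_form_posterior_oracle(x, y, priors, prior_mean=(50.0, -1.0))
        np.testing.assert_allclose(post.coef_mean, [50.0, -1.0], atol=1e-3)

    def test_collinear_design_raises(self):
        with pytest.raises(np.linalg.LinAlgError):
            closed_form_posterior_oracle([3.0, 3.0, 3.0], [1.0, 2.0, 3.0])


@pytest.fixture(scope="module")
def single_group_fit():
    x, y, ds = single_group_dataset(n=10, seed=42)
    draws = fit_gibbs(
        ds, mcmc=McmcConfig(n_iterations=6000, burn_in=2000, n_chains=2, seed=3)
    )
    return x, y, draws


class TestGibbsCorrectness:
    def test_posterior_matches_oracle_moments(self, single_group_fit):
        # Oracle vs sampler within 3x Monte-Carlo standard error.
        import arviz as az

        x, y, draws = single_group_fit
        oracle = closed_form_posterior_oracle(x, y)
        intercept = draws.alpha[:, 0, 0]
        slope = draws.beta[:, 0, 0, 0]
        for samples, target in ((intercept, oracle.coef_mean[0]),
                                (slope, oracle.coef_mean[1])):
            ess = float(az.ess(samples.reshape(2, -1)))
            mcse = samples.std(ddof=1) / np.sqrt(ess)
            assert abs(samples.mean() - target) < 3 * mcse

    def test_predictive_matches_student_t_at_large_n(self):
        # Prior families coincide in the data-dominated limit.
        x, y, ds = single_group_dataset(n=200, seed=8)
        draws = fit_gibbs(
            ds, mcmc=McmcConfig(n_iterations=4000, burn_in=1000, n_chains=1, seed=5)
        )
        oracle = closed_form_posterior_oracle(x, y)
        target = PredictionTarget("B01", "A", Container.VIAL, 5.0, 100.0)
        iv = predictive_interval(draws, target, alpha=0.05, seed=0)
        lo, center, hi = oracle.predictive_interval(100.0, 0.05)
        assert iv.center == pytest.approx(center, abs=0.4)
        assert iv.lower == pytest.approx(lo, abs=0.8)
        assert iv.upper == pytest.approx(hi, abs=0.8)

    def test_zero_noise_concentrates_on_true_slope(self):
        x = np.array([0.0, 3.0, 6.0, 9.0, 12.0])
        recs = [
            StabilityRecord(b, t, Container.VIAL, 5.0, float(ti), 100.0 - 0.5 * ti)
            for b in ("B01", "B02")
            for t in ("A", "B")
            for ti in x
        ]
        ds = StabilityDataset(recs)
        draws = fit_gibbs(
            ds, mcmc=McmcConfig(n_iterations=3000, burn_in=1000, n_chains=1, seed=1)
        )
        slopes = draws.beta[:, :, :, 0]
        assert np.abs(slopes.mean() + 0.5) < 0.01
        assert slopes.std() < 0.02

    def test_single_time_point_stratum_errors(self):
        recs = [
            StabilityRecord("B01", "A", Container.VIAL, 5.0, 0.0, 100.0),
            StabilityRecord("B01", "A", Container.VIAL, 5.0, 0.0, 101.0),
        ]
        ds = StabilityDataset(recs)
        with pytest.raises(ValueError, match="rank-deficient.*type=A"):
            fit_gibbs(ds)

    def test_empty_dataset_errors(self):
        with pytest.raises(ValueError, match="empty"):
            fit_gibbs(StabilityDataset([]))

    def test_seed_determinism(self, tiny_dataset):
        recs = tiny_dataset.records + [
            StabilityRecord("B01", "A", Container.VIAL, 5.0, 9.0, 97.0)
        ]
        ds = StabilityDataset(recs)
        mcmc = McmcConfig(n_iterations=200, burn_in=50, n_chains=2, seed=9)
        a = fit_gibbs(ds, mcmc=mcmc)
        b = fit_gibbs(ds, mcmc=mcmc)
        np.testing.assert_array_equal(a.beta, b.beta)
        np.testing.assert_array_equal(a.sigma2, b.sigma2)

    def test_draw_count_invariant(self, tiny_dataset):
        mcmc = McmcConfig(n_iterations=300, burn_in=100, thin=2, n_chains=3, seed=0)
        draws = fit_gibbs(tiny_dataset, mcmc=mcmc)
        assert draws.n_draws == mcmc.n_kept == 3 * (300 - 100) // 2
        assert (draws.sigma2 > 0).all()
        assert (draws.tau_a2 > 0).all()

    def test_parameter_recovery_on_default_cohort(self, fitted_default_draws,
                                                  default_params):
        draws = fitted_default_draws
        for k, temp in enumerate(draws.temperatures):
            truth = default_params.slope_mean_by_temp[temp]
            mean = draws.M[:, k].mean()
            sd = draws.M[:, k].std(ddof=1)
            assert abs(mean - truth) < 3 * sd, (temp, mean, truth, sd)
        # residual variance recovered
        sigma = np.sqrt(draws.sigma2.mean())
        assert sigma == pytest.approx(default_params.residual_sd, rel=0.1)

    def test_shrinkage_between_ols_and_type_mean(self):
        # Few observations per batch: batch slope posterior mean lies between
        # the stratum OLS slope and the type-level mean slope.
        rng = np.random.default_rng(17)
        t = np.array([0.0, 3.0, 6.0])
        recs = []
        true_slope = -0.5
        for b in range(12):
            slope = true_slope + rng.normal(0, 0.05)
            for ti in t:
                recs.append(
                    StabilityRecord(
                        f"B{b:02d}", "A", Container.VIAL, 5.0, float(ti),
                        float(100 + slope * ti + rng.normal(0, 2.0)),
                    )
                )
        ds = StabilityDataset(recs)
        draws = fit_gibbs(
            ds, mcmc=McmcConfig(n_iterations=3000, burn_in=1000, n_chains=1, seed=2)
        )
        frame = ds.to_frame()
        type_mean = draws.m[:, 0, 0].mean()
        n_between = 0
        for i, b in enumerate(draws.batch_ids):
            sub = frame[frame.batch_id == b]
            ols = ols_line(sub.time_months, sub.potency)[1]
            post = draws.beta[:, i, 0, 0].mean()
            lo, hi = sorted((ols, type_mean))
            if lo - 1e-9 <= post <= hi + 1e-9:
                n_between += 1
        assert n_between >= 10  # shrinkage for (almost) all batches


class TestArrheniusVariant:
    def test_extrapolation_to_unseen_temperature(self, default_training_cohort):
        draws = fit_gibbs(
            default_training_cohort,
            spec=ModelSpec(arrhenius_slopes=True),
            mcmc=McmcConfig(n_iterations=1500, burn_in=500, n_chains=1, seed=4),
        )
        assert draws.Ea is not None and (draws.Ea > 0).all()
        target = PredictionTarget(NEW_BATCH, "A", Container.VIAL, 42.0, 3.0)
        iv = predictive_interval(draws, target, alpha=0.05, seed=0)
        # hotter than 37C: mean potency at 3 months must sit below the 37C one
        t37 = PredictionTarget(NEW_BATCH, "A", Container.VIAL, 37.0, 3.0)
        iv37 = predictive_interval(draws, t37, alpha=0.05, seed=0)
        assert iv.center < iv37.center

    def test_plain_fit_refuses_unseen_temperature(self, fitted_default_draws):
        target = PredictionTarget(NEW_BATCH, "A", Container.VIAL, 42.0, 3.0)
        with pytest.raises(ValueError, match="extrapolation"):
            predictive_interval(fitted_default_draws, target)


class TestPredictiveInterval:
    def test_alpha_nesting(self, fitted_default_draws):
        target = PredictionTarget(NEW_BATCH, "A", Container.VIAL, 5.0, 24.0)
        wide = predictive_interval(fitted_default_draws, target, alpha=0.01, seed=0)
        narrow = predictive_interval(fitted_default_draws, target, alpha=0.05, seed=0)
        assert wide.lower < narrow.lower
        assert wide.upper > narrow.upper

    def test_mean_profile_center_at_t0(self, fitted_default_draws, default_params):
        draws = fitted_default_draws
        target = PredictionTarget(NEW_BATCH, "A", Container.SYRINGE, 5.0, 0.0)
        iv = predictive_interval(draws, target, alpha=0.05, kind="mean_profile",
                                 seed=0)
        j = draws.type_index("A")
        expected = (draws.a[:, j] + draws.gamma).mean()
        assert iv.center == pytest.approx(expected, abs=0.15)

    def test_predictive_wider_than_mean_profile(self, fitted_default_draws):
        target = PredictionTarget(NEW_BATCH, "A", Container.VIAL, 5.0, 12.0)
        pred = predictive_interval(fitted_default_draws, target, seed=0)
        prof = predictive_interval(fitted_default_draws, target,
                                   kind="mean_profile", seed=0)
        assert pred.width > prof.width

    def test_inflation_scales_width(self, default_training_cohort):
        mcmc = McmcConfig(n_iterations=800, burn_in=300, n_chains=1, seed=6)
        base = fit_gibbs(default_training_cohort, mcmc=mcmc)
        inflated = fit_gibbs(
            default_training_cohort,
            priors=PriorConfig(interval_inflation=2.0),
            mcmc=mcmc,
        )
        target = PredictionTarget(NEW_BATCH, "A", Container.VIAL, 5.0, 12.0)
        w0 = predictive_interval(base, target, seed=1).width
        w2 = predictive_interval(inflated, target, seed=1).width
        assert w2 == pytest.approx(2 * w0, rel=0.05)

    def test_invalid_alpha(self, fitted_default_draws):
        target = PredictionTarget(NEW_BATCH, "A", Container.VIAL, 5.0, 12.0)
        with pytest.raises(ValueError, match="alpha"):
            predictive_interval(fitted_default_draws, target, alpha=1.5)


def dogmatic_draws(intercept, slope, n=200):
    """Point-mass posterior: every draw equals the given line, all spreads 0."""
    D, B, T, K = n, 1, 1, 1
    return PosteriorDraws(
        batch_ids=("B01",),
        type_labels=("A",),
        temperatures=(5.0,),
        batch_container={"B01": Container.VIAL},
        mu=np.full(D, intercept),
        a=np.full((D, T), intercept),
        alpha=np.full((D, B, T), intercept),
        gamma=np.zeros(D),
        M=np.full((D, K), slope),
        m=np.full((D, T, K), slope),
        beta=np.full((D, B, T, K), slope),
        tau_a2=np.zeros(D),
        sigma_alpha2=np.zeros(D),
        tau_beta2=np.zeros(D),
        sigma_beta2=np.zeros(D),
        sigma2=np.zeros(D),
        chain=np.zeros(D, int),
    )


class TestShelfLife:
    def test_flat_truth_returns_horizon(self):
        draws = dogmatic_draws(100.0, 0.0)
        assert estimate_shelf_life(draws, "A", spec_limit=90.0, horizon=48) == 48

    def test_limit_above_t0_bound_returns_zero(self):
        draws = dogmatic_draws(100.0, -0.25)
        assert estimate_shelf_life(draws, "A", spec_limit=101.0) == 0

    def test_closed_form_crossing_time(self):
        # I + s*t >= limit until t = floor((limit - I)/s)
        draws = dogmatic_draws(100.0, -0.25)
        assert estimate_shelf_life(draws, "A", spec_limit=91.0, horizon=48) == 36
        assert estimate_shelf_life(draws, "A", spec_limit=90.9, horizon=48) == 36
        assert estimate_shelf_life(draws, "A", spec_limit=91.1, horizon=48) == 35

    def test_empty_draws_error(self):
        draws = dogmatic_draws(100.0, 0.0, n=0)
        with pytest.raises(ValueError, match="empty"):
            estimate_shelf_life(draws, "A")


class TestPosteriorSummary:
    def test_summary_moments_and_nesting(self, fitted_default_draws):
        s95 = posterior_summary(fitted_default_draws, 0.95).set_index("parameter")
        s50 = posterior_summary(fitted_default_draws, 0.5).set_index("parameter")
        assert (s95["lower"] <= s50["lower"] + 1e-12).all()
        assert (s95["upper"] >= s50["upper"] - 1e-12).all()
        # variance-component rows strictly positive
        for name in ("tau_a2", "sigma_alpha2", "tau_beta2", "sigma_beta2", "sigma2"):
            assert s95.loc[name, "lower"] > 0

    def test_mean_close_to_median_for_location_params(self, fitted_default_draws):
        draws = fitted_default_draws
        assert draws.mu.mean() == pytest.approx(np.median(draws.mu), abs=0.05)


class TestDrawsPersistence:
    def test_save_load_round_trip(self, fitted_default_draws, tmp_path):
        save_draws(fitted_default_draws, tmp_path / "d.csv", tmp_path / "m.json")
        loaded = load_draws(tmp_path / "d.csv", tmp_path / "m.json")
        np.testing.assert_allclose(loaded.beta, fitted_default_draws.beta)
        np.testing.assert_allclose(loaded.sigma2, fitted_default_draws.sigma2)
        assert loaded.batch_ids == fitted_default_draws.batch_ids
        assert loaded.batch_container == dict(fitted_default_draws.batch_container)
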