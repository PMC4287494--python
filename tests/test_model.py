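import numpy as np
import pytest

import spatmiss as sm
from spatmiss.data_io import DataValidationError
from spatmiss.model import ParamSummary, resolve_priors
from spatmiss.synthetic import default_truth

from conftest import make_dataset


class TestExpectedCounts:
    def test_uniform_prevalence(self):
        E = sm.expected_counts([10, 10], [100, 100])
        assert np.allclose(E, [10, 10])

    def test_exact_arithmetic(self):
        E = sm.expected_counts([5, 15], [100, 300])
        assert np.allclose(E, [5, 15])  # pbar = 0.05

    def test_observed_totals_balance(self):
        rng = np.random.default_rng(0)
        n = rng.integers(50, 5000, size=40)
        Y = rng.poisson(0.1 * n).astype(float)
        Y[[3, 11]] = np.nan
        E = sm.expected_counts(Y, n)
        obs = ~np.isnan(Y)
        assert E[obs].sum() == pytest.approx(Y[obs].sum(), rel=1e-12)

    def test_all_missing_rejected(self):
        with pytest.raises(DataValidationError):
            sm.expected_counts([np.nan, np.nan], [10, 10])


class TestDIC:
    def test_point_mass_posterior_has_zero_pd(self):
        d = sm.compute_dic([12.0, 12.0, 12.0], 12.0)
        assert d.pD == 0.0 and d.DIC == d.Dbar == 12.0

    def test_arithmetic(self):
        d = sm.compute_dic([10.0, 14.0], 11.0)
        assert (d.Dbar, d.pD, d.DIC) == (12.0, 1.0, 13.0)

    def test_empty_draws_rejected(self):
        with pytest.raises(ValueError):
            sm.compute_dic([], 0.0)

    def test_noise_covariate_adds_about_one_effective_parameter(self):
        # plain Bayesian GLM (random effects off): adding a pure-noise
        # covariate should raise pD by ~1
        lat = sm.make_grid_lattice(6, 6)
        truth = default_truth(seed=3, beta=np.zeros(7), sigma_U=0.0, sigma_S=0.0)
        data, _ = sm.simulate_dataset(lat, truth, seed=3)
        null = make_dataset(np.empty((36, 0)), lattice=lat, Y=data.Y, n=data.n)
        rng = np.random.default_rng(4)
        noisy = make_dataset(
            rng.standard_normal((36, 1)), lattice=lat, Y=data.Y, n=data.n
        )
        cfg = dict(family="poisson", imputation="none", iters=3000, burnin=1000,
                   chains=2, seed=3, include_random_effects=False)
        fit0 = sm.fit_spatial_glmm(null, sm.ModelConfig(**cfg))
        fit1 = sm.fit_spatial_glmm(noisy, sm.ModelConfig(**cfg))
        assert fit1.dic.pD - fit0.dic.pD == pytest.approx(1.0, abs=0.5)


class TestSignificanceFlags:
    @pytest.mark.parametrize(
        "lo,hi,expected",
        [
            (-0.240, -0.143, True),   # interval fully below zero
            (-0.001, 0.020, False),   # straddles zero
            (0.0, 0.5, False),        # boundary: zero endpoint is not exclusion
            (0.1, 0.5, True),
        ],
    )
    def test_zero_exclusion_rule(self, lo, hi, expected):
        assert sm.significance_flags([lo], [hi])[0] == expected


class TestRelativeExcessRisk:
    def test_null_residual_gives_unit_rer(self):
        df = sm.relative_excess_risk(np.zeros((50, 4)), np.zeros((50, 4)))
        assert np.allclose(df["mean"], 1.0)

    def test_log_two_residual(self):
        U = np.full((20, 3), np.log(2) / 2)
        S = np.full((20, 3), np.log(2) / 2)
        df = sm.relative_excess_risk(U, S)
        assert np.allclose(df["mean"], 2.0)

    def test_summary_matches_brute_force_average(self):
        rng = np.random.default_rng(5)
        U, S = rng.normal(size=(200, 6)), rng.normal(size=(200, 6))
        df = sm.relative_excess_risk(U, S)
        brute = np.exp(U + S).mean(axis=0)
        assert np.allclose(df["mean"], brute, atol=1e-12)


class TestPriorResolution:
    def test_all_models_resolve(self):
        for m in range(1, 6):
            pr = resolve_priors(m)
            assert pr["sigma_S"] in ("gamma", "uniform")
        assert resolve_priors(4)["halfnormal_var"] == 0.0625
        assert resolve_priors(4, halfnormal_is_variance=False)["halfnormal_var"] == 16.0

    def test_bad_model_rejected(self):
        with pytest.raises(ValueError):
            sm.ModelConfig(prior_model=6)


class TestFitting:
    def test_alpha_only_model_matches_quadrature_oracle(self):
        # random effects off, no covariates: p(alpha | Y) is a 1-D posterior
        # we can integrate on a fine grid and compare with MCMC
        lat = sm.make_grid_lattice(2, 3)
        Y = np.array([12.0, 9.0, 15.0, 7.0, 11.0, 13.0])
        n = np.full(6, 1000)
        data = make_dataset(np.empty((6, 0)), lattice=lat, Y=Y, n=n)
        cfg = sm.ModelConfig(family="poisson", imputation="none", iters=6000,
                             burnin=2000, chains=2, seed=1,
                             include_random_effects=False)
        summ = sm.fit_spatial_glmm(data, cfg)
        E = sm.expected_counts(Y, n)
        grid = np.linspace(-1.0, 1.0, 20001)
        loglik = np.sum(Y[:, None] * grid[None, :] - E[:, None] * np.exp(grid)[None, :], axis=0)
        logpost = loglik - grid**2 / (2 * 100.0)
        w = np.exp(logpost - logpost.max())
        w /= w.sum()
        alpha_mean = float(np.sum(w * grid))
        assert summ.alpha.mean == pytest.approx(alpha_mean, abs=0.01)

    def test_null_data_recovery_no_significance(self):
        lat = sm.make_study_lattice(71)
        truth = default_truth(seed=2, beta=np.zeros(7), sigma_U=0.0, sigma_S=0.0)
        data, _ = sm.simulate_dataset(lat, truth, seed=2)
        summ = sm.fit_spatial_glmm(
            data, sm.ModelConfig(family="poisson", imputation="none", prior_model=1,
                                 iters=3000, burnin=1500, chains=2, seed=2)
        )
        for b in summ.beta:
            assert b.lo <= 0.0 <= b.hi
        assert not summ.significant.any()

    def test_sum_to_zero_constraint_every_draw(self, complete_study_data):
        data, _ = complete_study_data
        summ = sm.fit_spatial_glmm(
            data, sm.ModelConfig(imputation="none", iters=1500, burnin=500,
                                 chains=1, seed=4)
        )
        assert np.abs(summ.draws["S"].mean(axis=1)).max() < 1e-8

    def test_rr_positive_and_near_one_on_average(self, complete_study_data):
        data, _ = complete_study_data
        summ = sm.fit_spatial_glmm(
            data, sm.ModelConfig(imputation="none", iters=2000, burnin=1000,
                                 chains=1, seed=4)
        )
        assert (summ.RR["mean"] > 0).all() and (summ.RER["mean"] > 0).all()
        assert summ.RR["mean"].mean() == pytest.approx(1.0, abs=0.25)
        # credible interval ordering holds everywhere
        assert (summ.RR["lo"] <= summ.RR["mean"]).all()
        assert (summ.RR["mean"] <= summ.RR["hi"]).all()

    def test_binomial_poisson_concordance_low_prevalence(self, complete_study_data):
        data, truth = complete_study_data
        fits = {}
        for family in ("poisson", "binomial"):
            d, _ = sm.make_study_dataset(seed=7, missingness=False, family=family)
            fits[family] = sm.fit_spatial_glmm(
                d, sm.ModelConfig(family=family, imputation="none", iters=3000,
                                  burnin=1500, chains=2, seed=7)
            )
        b_p = fits["poisson"].beta[0]
        b_b = fits["binomial"].beta[0]
        assert max(b_p.lo, b_b.lo) <= min(b_p.hi, b_b.hi), (
            "SES coefficient CrIs from the two families should overlap"
        )
        assert np.sign(b_p.mean) == np.sign(b_b.mean)

    def test_joint_imputation_widens_rr_for_masked_regions(self, study_data):
        data, _ = study_data
        cfg = dict(family="poisson", iters=2500, burnin=1000, chains=2, seed=7)
        fit_mean = sm.fit_spatial_glmm(data, sm.ModelConfig(imputation="mean", **cfg))
        fit_car = sm.fit_spatial_glmm(data, sm.ModelConfig(imputation="car_joint", **cfg))
        masked = data.mask.any(axis=1)
        w_mean = (fit_mean.RR["hi"] - fit_mean.RR["lo"])[masked].mean()
        w_car = (fit_car.RR["hi"] - fit_car.RR["lo"])[masked].mean()
        assert w_car > w_mean

    def test_missing_outcome_regions_still_get_risk_estimates(self, study_data):
        data, _ = study_data
        assert np.isnan(data.Y).sum() == 4
        summ = sm.fit_spatial_glmm(
            data, sm.ModelConfig(imputation="mean", iters=1500, burnin=500,
                                 chains=1, seed=1)
        )
        miss = np.isnan(data.Y)
        assert np.isfinite(summ.RR["mean"][miss]).all()
        assert np.isfinite(summ.RER["mean"][miss]).all()

    def test_incomplete_data_with_none_imputation_rejected(self, study_data):
        data, _ = study_data
        with pytest.raises(DataValidationError):
            sm.fit_spatial_glmm(data, sm.ModelConfig(imputation="none"))


class TestParamSummary:
    def test_interval_ordering(self):
        rng = np.random.default_rng(1)
        s = ParamSummary.from_draws(rng.normal(2.0, 1.0, size=1000))
        assert s.lo <= s.mean <= s.hi
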