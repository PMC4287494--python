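import numpy as np
import pytest

import spatmiss as sm
from spatmiss.data_io import DataValidationError, RegionLattice
from spatmiss.imputation import MCMCSettings

from conftest import make_dataset

FAST = MCMCSettings(iters=1200, burnin=400, chains=2)


class TestMeanImputation:
    def test_arithmetic_mean(self):
        data = make_dataset([[2.0], [4.0], [np.nan]])
        res = sm.impute_mean(data)
        assert res.point[("R2", "c0")] == 3.0
        lo, hi = res.interval[("R2", "c0")]
        assert lo == 3.0 == hi  # degenerate interval

    def test_completed_mean_equals_observed_mean_exactly(self, study_data):
        data, _ = study_data
        res = sm.impute_mean(data)
        for j in range(data.n_covariates):
            obs = ~data.mask[:, j]
            if obs.all():
                continue
            assert res.completed.X[:, j].mean() == pytest.approx(
                data.X[obs, j].mean(), abs=1e-12
            )

    def test_deflates_column_sd(self, study_data):
        data, _ = study_data
        res = sm.impute_mean(data)
        for j in range(data.n_covariates):
            obs = ~data.mask[:, j]
            if obs.all():
                continue
            assert res.completed.X[:, j].std() <= data.X[obs, j].std()

    def test_observed_cells_untouched(self, study_data):
        data, _ = study_data
        res = sm.impute_mean(data)
        assert np.array_equal(res.completed.X[~data.mask], data.X[~data.mask])

    def test_fully_missing_column_rejected(self):
        data = make_dataset([[np.nan, 1.0], [np.nan, 2.0]])
        with pytest.raises(DataValidationError):
            sm.impute_mean(data)


class TestMVNImputation:
    def test_no_masked_cells_is_identity(self):
        data = make_dataset(np.random.default_rng(0).normal(size=(10, 3)))
        res = sm.impute_mvn(data, mcmc=FAST, seed=0)
        assert res.point == {}
        assert np.array_equal(res.completed.X, data.X)

    def test_bivariate_conditional_mean_oracle(self):
        # two highly correlated covariates; the posterior mean of a masked
        # cell must track the closed-form Gaussian conditional
        # mu1 + rho*(s1/s2)*(x2 - mu2) computed from sample moments
        rng = np.random.default_rng(3)
        n = 120
        z = rng.standard_normal(n)
        x1 = 2.0 + 1.0 * z
        x2 = -1.0 + 0.5 * (0.99 * z + np.sqrt(1 - 0.99**2) * rng.standard_normal(n))
        X = np.column_stack([x1, x2])
        miss_row = 17
        X_missing = X.copy()
        X_missing[miss_row, 0] = np.nan
        data = make_dataset(X_missing)
        res = sm.impute_mvn(data, mcmc=MCMCSettings(3000, 1000, 2), seed=1)
        obs = np.delete(np.arange(n), miss_row)
        mu = X[obs].mean(axis=0)
        cov = np.cov(X[obs].T)
        cond = mu[0] + cov[0, 1] / cov[1, 1] * (X[miss_row, 1] - mu[1])
        sd1 = np.sqrt(cov[0, 0])
        assert res.point[(f"R{miss_row}", "c0")] == pytest.approx(cond, abs=0.1 * sd1)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_beats_mean_on_strongly_correlated_data(self, seed):
        rng = np.random.default_rng(seed)
        n, p = 200, 3
        z = rng.standard_normal(n)
        lam = 0.9
        X = lam * z[:, None] + np.sqrt(1 - lam**2) * rng.standard_normal((n, p))
        assert np.abs(np.corrcoef(X.T)[np.triu_indices(p, 1)]).max() >= 0.7
        mask = rng.random((n, p)) < 0.1
        # keep at least one observed cell per row to stay in the MAR regime
        full_rows = ~mask.any(axis=1)
        Xm = np.where(mask, np.nan, X)
        data = make_dataset(Xm)
        res_mvn = sm.impute_mvn(data, mcmc=FAST, seed=seed)
        res_mean = sm.impute_mean(data)

        def rmse(res):
            errs = [
                res.point[(f"R{i}", f"c{j}")] - X[i, j]
                for i, j in zip(*np.nonzero(mask))
            ]
            return np.sqrt(np.mean(np.square(errs)))

        assert rmse(res_mvn) < rmse(res_mean)

    def test_seed_reproducible(self, study_data):
        data, _ = study_data
        a = sm.impute_mvn(data, mcmc=FAST, seed=5)
        b = sm.impute_mvn(data, mcmc=FAST, seed=5)
        assert a.point == b.point


def chain_lattice(n):
    ids = [f"N{i}" for i in range(n)]
    return RegionLattice.from_edges(ids, [(f"N{i}", f"N{i+1}") for i in range(n - 1)])


class TestCARImputation:
    def test_three_node_chain_matches_exact_conditional(self):
        # A - B - C with A=0, C=10 observed: the intrinsic CAR conditional
        # for B is N((A+C)/2, sigma^2/m_B); posterior mean must be ~5
        lat = chain_lattice(3)
        X = np.array([[0.0], [np.nan], [10.0]])
        data = make_dataset(X, lattice=lat)
        res = sm.impute_car(data, mcmc=MCMCSettings(4000, 1000, 2), seed=2)
        assert res.point[("N1", "c0")] == pytest.approx(5.0, abs=0.35)
        # the marginal posterior (spatial variance integrated out) is a
        # heavy-tailed distribution symmetric about 5
        lo, hi = res.interval[("N1", "c0")]
        assert lo < 5.0 < hi
        assert (5.0 - lo) == pytest.approx(hi - 5.0, abs=1.5)

    def test_constant_neighbourhood_recovers_constant(self, grid3x3):
        X = np.full((9, 1), 7.0)
        X[4, 0] = np.nan  # centre region, all four neighbours observed at 7
        data = make_dataset(X, lattice=grid3x3)
        res = sm.impute_car(data, mcmc=FAST, seed=0)
        assert res.point[(grid3x3.region_ids[4], "c0")] == pytest.approx(7.0, abs=0.05)

    def test_masked_neighbourhood_widens_interval(self):
        # same field; one masked cell surrounded by observed data vs a
        # masked block whose interior has no observed neighbour
        lat = sm.make_grid_lattice(5, 5)
        rng = np.random.default_rng(4)
        vals = sm.sample_car_field(lat, 1.0, seed=8) + 5.0
        X = vals[:, None].copy()
        isolated = 12  # centre: all neighbours observed
        block = [0, 1, 5, 6]  # corner block: cell 0's neighbours all masked
        X[isolated, 0] = np.nan
        for i in block:
            X[i, 0] = np.nan
        data = make_dataset(X, lattice=lat)
        res = sm.impute_car(data, mcmc=MCMCSettings(3000, 1000, 2), seed=3)
        w_isolated = res.interval_width((lat.region_ids[isolated], "c0"))
        w_blocked = res.interval_width((lat.region_ids[0], "c0"))
        assert w_blocked > w_isolated
        assert (lat.region_ids[0], "c0") in res.metadata["prior_dominated"]

    def test_observed_cells_untouched_and_reproducible(self, study_data):
        data, _ = study_data
        a = sm.impute_car(data, mcmc=FAST, seed=9)
        b = sm.impute_car(data, mcmc=FAST, seed=9)
        assert np.array_equal(a.completed.X[~data.mask], data.X[~data.mask])
        assert a.point == b.point

    def test_doubling_iterations_stable_posterior_mean(self, grid3x3):
        X = np.arange(9, dtype=float)[:, None]
        X[4, 0] = np.nan
        data = make_dataset(X, lattice=grid3x3)
        short = sm.impute_car(data, mcmc=MCMCSettings(2000, 500, 2), seed=1)
        long = sm.impute_car(data, mcmc=MCMCSettings(4000, 500, 2), seed=1)
        k = (grid3x3.region_ids[4], "c0")
        assert short.point[k] == pytest.approx(long.point[k], abs=0.1)


class TestDirectionalAdvantages:
    def test_car_beats_mean_on_smooth_fields(self):
        # spatially smooth covariate, MCAR missingness: neighbours carry
        # the signal, so CAR imputation should win on RMSE
        lat = sm.make_grid_lattice(8, 8)
        rng = np.random.default_rng(6)
        truth_vals = sm.sample_car_field(lat, 2.0, seed=6) + 10.0
        mask = rng.random(64) < 0.2
        X = np.where(mask, np.nan, truth_vals)[:, None]
        data = make_dataset(X, lattice=lat)
        res_car = sm.impute_car(data, mcmc=FAST, seed=6)
        res_mean = sm.impute_mean(data)

        def rmse(res):
            errs = [
                res.point[(lat.region_ids[i], "c0")] - truth_vals[i]
                for i in np.nonzero(mask)[0]
            ]
            return np.sqrt(np.mean(np.square(errs)))

        assert rmse(res_car) < rmse(res_mean)
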