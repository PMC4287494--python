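"""Bayesian spatial GLMMs for areal disease risk.

The model: for region ``i`` with case count ``Y_i``,

* binomial: ``Y_i ~ Bin(n_i, p_i)`` with ``logit(p_i) = alpha + x_i beta + U_i + S_i``
* poisson:  ``Y_i ~ Pois(E_i lambda_i)`` with ``log(lambda_i) = alpha + x_i beta + U_i + S_i``

``U_i`` is an exchangeable normal ("unstructured") random effect and ``S_i``
an intrinsic CAR ("structured") spatial effect: conditionally, ``S_i`` is
normal about the mean of its neighbours' values with variance
``sigma_S^2 / m_i``, identified by a sum-to-zero constraint. Splitting the
residual this way separates risk variation that clusters in space from
region-specific noise. Expected counts ``E_i`` use internal
standardisation (state-wide prevalence times population), so the relative
risk ``lambda_i`` averages about 1 and the relative excess risk
``RER_i = exp(U_i + S_i)`` measures risk left unexplained by the covariates.

Inference is Metropolis-within-Gibbs: adaptive random-walk updates for the
intercept and coefficients, vectorised random-walk updates for ``U``,
colour-blocked updates for ``S`` (regions of one colour are conditionally
independent under the ICAR prior), conjugate Gamma updates for precisions,
and grid-based draws for the bounded / half-normal / log-normal standard
deviation priors of the sensitivity grid. Missing covariate cells can be
sampled jointly with the model (their prior full conditional is the
proposal; the outcome likelihood supplies the Metropolis correction), and
missing outcomes are drawn from the posterior predictive.
"""

from __future__ import annotations

from collections import namedtuple
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln

from .data_io import (
    DataValidationError,
    RegionDataset,
    center_covariates,
)
from .imputation import impute_mean

DICResult = namedtuple("DICResult", ["Dbar", "pD", "DIC"])

RHAT_WARN = 1.05


# ---------------------------------------------------------------------------
# expected counts (internal standardisation)


def expected_counts(Y: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Expected counts from internal standardisation.

    The state-wide prevalence ``pbar`` is the ratio of total observed cases
    to the population of regions with an observed count; ``E_i = pbar * n_i``
    for every region (including those with a missing count). By construction
    the expected counts of observed regions sum exactly to their cases.
    """
    Y = np.asarray(Y, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(n <= 0):
        raise DataValidationError("populations must be positive")
    obs = ~np.isnan(Y)
    if not obs.any():
        raise DataValidationError("cannot standardise: all case counts missing")
    pbar = Y[obs].sum() / n[obs].sum()
    return pbar * n


def with_expected_counts(data: RegionDataset) -> RegionDataset:
    """Return a copy of ``data`` with ``E`` filled in."""
    out = data.copy()
    out.E = expected_counts(out.Y, out.n)
    return out


# ---------------------------------------------------------------------------
# configuration


@dataclass
class ModelConfig:
    """Settings for one GLMM fit.

    ``prior_model`` selects one of five prior configurations used in the
    sensitivity grid (all share a vague N(0, variance 100) intercept prior,
    written N(0, 0.01) in precision notation):

    1. baseline — Gamma(1, 0.01) priors on the precisions of ``beta`` and
       ``U``; intrinsic CAR on ``S`` with Gamma(1, 0.01) precision
       (missing covariates, if sampled jointly, get CAR priors);
    2. as 1 with normal coefficient priors (identical precision structure);
    3. Uniform(0.01, 5) priors on the standard deviations of ``beta``,
       ``U`` and ``S``;
    4. half-normal prior on the standard deviation of ``U`` (scale 0.0625,
       read as a variance by default, i.e. sd 0.25);
    5. log-normal prior on the standard deviation of ``U``
       (``log sigma_U ~ N(0, 4)``).

    ``imputation`` controls how missing covariate cells are handled:
    ``"none"`` requires complete data, ``"mean"`` completes the data with
    observed column means before fitting, ``"mvn_joint"`` and ``"car_joint"``
    sample the missing cells inside the MCMC under a multivariate-normal or
    per-covariate CAR prior respectively.
    """

    family: str = "poisson"
    imputation: str = "mean"
    prior_model: int = 1
    iters: int = 4000
    burnin: int = 2000
    chains: int = 2
    seed: int = 0
    center: "tuple | None" = None  # None -> survey/age default subset
    halfnormal_is_variance: bool = True
    #: drop U and S entirely (plain Bayesian GLM); used for reduced-model
    #: checks where the posterior is tractable by quadrature
    include_random_effects: bool = True

    def __post_init__(self) -> None:
        if self.family not in ("binomial", "poisson"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.imputation not in ("none", "mean", "mvn_joint", "car_joint"):
            raise ValueError(f"unknown imputation mode {self.imputation!r}")
        if self.prior_model not in (1, 2, 3, 4, 5):
            raise ValueError("prior_model must be in 1..5")
        if not self.iters > self.burnin >= 0:
            raise ValueError("need iters > burnin >= 0")
        if self.chains < 1:
            raise ValueError("need >= 1 chain")


def resolve_priors(prior_model: int, halfnormal_is_variance: bool = True) -> dict:
    """Map a prior-configuration number to concrete prior families."""
    base = {"alpha_var": 100.0, "gamma_shape": 1.0, "gamma_rate": 0.01}
    if prior_model in (1, 2):
        return {**base, "beta": "gamma", "sigma_U": "gamma", "sigma_S": "gamma"}
    if prior_model == 3:
        return {**base, "beta": "uniform", "sigma_U": "uniform", "sigma_S": "uniform"}
    if prior_model == 4:
        hv = 0.0625 if halfnormal_is_variance else 1.0 / 0.0625
        return {**base, "beta": "gamma", "sigma_U": "halfnormal", "sigma_S": "gamma",
                "halfnormal_var": hv}
    if prior_model == 5:
        return {**base, "beta": "gamma", "sigma_U": "lognormal", "sigma_S": "gamma",
                "lognormal_var": 4.0}
    raise ValueError("prior_model must be in 1..5")


# ---------------------------------------------------------------------------
# posterior containers


@dataclass(frozen=True)
class ParamSummary:
    mean: float
    sd: float
    lo: float
    hi: float

    @classmethod
    def from_draws(cls, x: np.ndarray) -> "ParamSummary":
        return cls(
            mean=float(np.mean(x)),
            sd=float(np.std(x, ddof=1)) if len(x) > 1 else 0.0,
            lo=float(np.percentile(x, 2.5)),
            hi=float(np.percentile(x, 97.5)),
        )


@dataclass
class PosteriorSummary:
    """Posterior means, 95% credible intervals and diagnostics of one fit."""

    family: str
    prior_model: int
    covariate_names: tuple
    region_ids: tuple
    alpha: ParamSummary
    beta: tuple
    sigma_S2: ParamSummary
    sigma_U2: ParamSummary
    RR: pd.DataFrame
    RER: pd.DataFrame
    dic: DICResult
    rhat: dict
    significant: np.ndarray
    draws: dict = dc_field(default_factory=dict)
    warnings: list = dc_field(default_factory=list)

    def beta_frame(self) -> pd.DataFrame:
        rows = [
            {
                "covariate": c,
                "mean": b.mean,
                "sd": b.sd,
                "lo": b.lo,
                "hi": b.hi,
                "significant": bool(s),
            }
            for c, b, s in zip(self.covariate_names, self.beta, self.significant)
        ]
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "prior_model": self.prior_model,
            "alpha": vars(self.alpha),
            "beta": [vars(b) for b in self.beta],
            "sigma_S2": vars(self.sigma_S2),
            "sigma_U2": vars(self.sigma_U2),
            "dic": {"Dbar": self.dic.Dbar, "pD": self.dic.pD, "DIC": self.dic.DIC},
            "rhat": self.rhat,
            "significant": [bool(s) for s in self.significant],
            "warnings": list(self.warnings),
        }


def compute_dic(deviance_draws, theta_bar_deviance: float) -> DICResult:
    """Classic DIC: ``Dbar + pD`` with ``pD = Dbar - D(theta_bar)``.

    ``Dbar`` is the posterior mean deviance (goodness of fit) and ``pD``
    the effective number of parameters, the gap between the mean deviance
    and the deviance at the posterior means ("plug-in"). Smaller DIC
    indicates a better-supported model.
    """
    deviance_draws = np.asarray(deviance_draws, dtype=float)
    if deviance_draws.size == 0:
        raise ValueError("DIC needs at least one deviance draw")
    Dbar = float(deviance_draws.mean())
    pD = Dbar - float(theta_bar_deviance)
    return DICResult(Dbar=Dbar, pD=pD, DIC=Dbar + pD)


def relative_excess_risk(U_draws: np.ndarray, S_draws: np.ndarray, region_ids=None) -> pd.DataFrame:
    """Per-region relative excess risk summaries from posterior draws.

    ``RER_i = exp(U_i + S_i)`` per draw: the residual risk multiplier after
    the covariate effects are accounted for. ``RER = 1`` means the region's
    risk is fully explained by its covariates.
    """
    U_draws = np.atleast_2d(np.asarray(U_draws, dtype=float))
    S_draws = np.atleast_2d(np.asarray(S_draws, dtype=float))
    if U_draws.shape != S_draws.shape:
        raise ValueError("U and S draws must have matching shapes")
    rer = np.exp(U_draws + S_draws)
    return _risk_frame(rer, region_ids)


def _risk_frame(draws_kn: np.ndarray, region_ids=None) -> pd.DataFrame:
    n = draws_kn.shape[1]
    ids = list(region_ids) if region_ids is not None else list(range(n))
    return pd.DataFrame(
        {
            "region_id": ids,
            "mean": draws_kn.mean(axis=0),
            "sd": draws_kn.std(axis=0, ddof=1) if draws_kn.shape[0] > 1 else 0.0,
            "lo": np.percentile(draws_kn, 2.5, axis=0),
            "hi": np.percentile(draws_kn, 97.5, axis=0),
        }
    )


def significance_flags(lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """A coefficient is significant iff its 95% CrI excludes zero (strictly)."""
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    return (lo > 0) | (hi < 0)


# ---------------------------------------------------------------------------
# internal sampler machinery


def _greedy_coloring(neighbors) -> list:
    """Colour classes such that no two neighbours share a colour."""
    n = len(neighbors)
    color = np.full(n, -1, dtype=int)
    for i in range(n):
        used = {color[k] for k in neighbors[i] if color[k] >= 0}
        c = 0
        while c in used:
            c += 1
        color[i] = c
    return [np.nonzero(color == c)[0] for c in range(color.max() + 1)]


def _sigma_grid(kind: str, priors: dict) -> np.ndarray:
    if kind == "uniform":
        return np.linspace(0.01, 5.0, 400)
    return np.exp(np.linspace(np.log(1e-3), np.log(20.0), 400))


def _log_sigma_prior(kind: str, sigma: np.ndarray, priors: dict) -> np.ndarray:
    if kind == "uniform":
        return np.zeros_like(sigma)
    if kind == "halfnormal":
        return -0.5 * sigma**2 / priors["halfnormal_var"]
    if kind == "lognormal":
        return -0.5 * np.log(sigma) ** 2 / priors["lognormal_var"] - np.log(sigma)
    raise ValueError(kind)


def _draw_sigma_grid(rng, kind, priors, ssq: float, k: int) -> float:
    """Grid draw of a standard deviation with posterior ~ sigma^-k exp(-ssq/2s^2) * prior."""
    grid = _sigma_grid(kind, priors)
    lp = -k * np.log(grid) - 0.5 * ssq / grid**2 + _log_sigma_prior(kind, grid, priors)
    lp -= lp.max()
    w = np.exp(lp)
    w /= w.sum()
    return float(rng.choice(grid, p=w))


def _draw_precision(rng, kind, priors, ssq: float, k: int) -> float:
    """Draw precision 1/sigma^2 given sum of squares ``ssq`` over ``k`` terms."""
    if kind == "gamma":
        return float(
            rng.gamma(priors["gamma_shape"] + 0.5 * k, 1.0 / (priors["gamma_rate"] + 0.5 * ssq))
        )
    sigma = _draw_sigma_grid(rng, kind, priors, ssq, k)
    return 1.0 / sigma**2


class _AdaptiveMVN:
    """Haario-style adaptive multivariate proposal, frozen after burn-in."""

    def __init__(self, dim: int, burnin: int):
        self.dim = dim
        self.burnin = burnin
        self.count = 0
        self.mean = np.zeros(dim)
        self.M2 = np.zeros((dim, dim))
        self.chol = 0.01 * np.eye(dim)
        self.accepted = 0

    def update(self, theta: np.ndarray) -> None:
        if self.count >= self.burnin:
            return
        self.count += 1
        d = theta - self.mean
        self.mean += d / self.count
        self.M2 += np.outer(d, theta - self.mean)
        if self.count >= 50 and self.count % 25 == 0:
            cov = self.M2 / (self.count - 1)
            cov = (2.38**2 / self.dim) * cov + 1e-10 * np.eye(self.dim)
            try:
                self.chol = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError:
                pass

    def propose(self, rng, theta: np.ndarray) -> np.ndarray:
        return theta + self.chol @ rng.standard_normal(self.dim)


class _Likelihood:
    """Per-region log-likelihood kernels and full deviance for one family."""

    def __init__(self, family, Y, n, E, y_obs):
        self.family = family
        self.Y = np.where(y_obs, np.nan_to_num(Y), 0.0)
        self.n = np.asarray(n, dtype=float)
        self.E = E
        self.w = y_obs.astype(float)
        if family == "poisson":
            self.const = -gammaln(self.Y + 1.0) + self.Y * np.log(E)
        else:
            self.const = gammaln(self.n + 1) - gammaln(self.Y + 1) - gammaln(self.n - self.Y + 1)

    def kernel(self, eta: np.ndarray) -> np.ndarray:
        """Unnormalised per-region log-likelihood (0 for missing Y)."""
        if self.family == "poisson":
            ll = self.Y * eta - self.E * np.exp(eta)
        else:
            ll = self.Y * eta - self.n * np.logaddexp(0.0, eta)
        return self.w * ll

    def deviance(self, eta: np.ndarray) -> float:
        """Full -2 log-likelihood over regions with observed counts."""
        return float(-2.0 * np.sum(self.kernel(eta) + self.w * self.const))

    def predictive(self, rng, eta: np.ndarray) -> np.ndarray:
        if self.family == "poisson":
            return rng.poisson(self.E * np.exp(eta)).astype(float)
        return rng.binomial(self.n.astype(int), expit(eta)).astype(float)


def _prepare_joint_imputation(data, mode):
    """Static structures for sampling missing covariate cells in the MCMC."""
    info = {"mode": mode}
    mask = data.mask
    if not mask.any():
        info["mode"] = "none"
        return info
    if mode == "mvn_joint":
        from .imputation import _pattern_groups

        info["groups"] = _pattern_groups(mask)
        info["psi"] = np.full((data.n_covariates,) * 2, 0.001)
        np.fill_diagonal(info["psi"], 0.01)
        info["nu"] = data.n_covariates
    elif mode == "car_joint":
        if data.lattice is None:
            raise DataValidationError("car_joint imputation needs a lattice on the dataset")
        info["W"] = data.lattice.adjacency_matrix()
        info["m"] = data.lattice.m.astype(float)
        info["Q"] = data.lattice.icar_precision()
        info["mis_cols"] = {
            j: np.nonzero(mask[:, j])[0]
            for j in range(data.n_covariates)
            if mask[:, j].any()
        }
    return info


def _run_chain(data, config, priors, chain_seed, lik, joint):
    rng = np.random.default_rng(chain_seed)
    N, p = data.X.shape
    X = data.X.copy()
    mask = data.mask
    # start missing cells at observed column means
    for j in range(p):
        if mask[:, j].any():
            X[mask[:, j], j] = X[~mask[:, j], j].mean()

    # crude empirical initialisation keeps the burn-in walk short
    if lik.family == "binomial":
        crude = lik.Y[lik.w > 0].sum() / lik.n[lik.w > 0].sum()
        alpha = float(np.log(crude / (1.0 - crude))) if 0 < crude < 1 else 0.0
    else:
        alpha = 0.0
    beta = np.zeros(p)
    u = np.zeros(N)
    S = np.zeros(N)
    tau_U = 1.0 / 0.1
    tau_S = 1.0 / 0.1
    tau_beta = np.ones(p)
    tau_v = np.ones(p)  # car_joint spatial precisions per covariate
    M = X.mean(axis=0)
    Sigma = np.cov(X.T) + 1e-8 * np.eye(p)

    m = data.lattice.m.astype(float) if data.lattice is not None else None
    W = data.lattice.adjacency_matrix() if data.lattice is not None else None
    Q = data.lattice.icar_precision() if data.lattice is not None else None
    colors = _greedy_coloring(data.lattice.neighbors) if data.lattice is not None else None

    eta = alpha + X @ beta + u + S

    adapt = _AdaptiveMVN(p + 1, config.burnin)

    # adaptive random-walk scales
    s_alpha, s_beta = 0.1, np.full(p, 0.05)
    s_u = np.full(N, 0.2)
    s_S = np.full(N, 0.2)
    s_ridge = np.full(p, 0.05)
    s_ridge_u = np.full(p, 0.05)
    acc_alpha = 0
    acc_beta = np.zeros(p)
    acc_u = np.zeros(N)
    acc_S = np.zeros(N)
    acc_ridge = np.zeros(p)
    acc_ridge_u = np.zeros(p)
    x_static = None
    ADAPT_EVERY = 50

    kept = config.iters - config.burnin
    store = {
        "alpha": np.empty(kept),
        "beta": np.empty((kept, p)),
        "sigma_U2": np.empty(kept),
        "sigma_S2": np.empty(kept),
        "U": np.empty((kept, N)),
        "S": np.empty((kept, N)),
        "eta": np.empty((kept, N)),
        "deviance": np.empty(kept),
        "X_missing_sum": np.zeros((N, p)),
    }

    alpha_var = priors["alpha_var"]

    for t in range(config.iters):
        # --- missing covariate cells ---
        if joint["mode"] == "mvn_joint":
            xbar = X.mean(axis=0)
            M = rng.multivariate_normal(xbar, Sigma / N, method="cholesky")
            dev = X - M
            from scipy.stats import wishart

            scale = np.linalg.inv(joint["psi"] + dev.T @ dev)
            Omega = wishart.rvs(df=joint["nu"] + N, scale=(scale + scale.T) / 2, random_state=rng)
            Sigma = np.linalg.inv(Omega)
            Sigma = (Sigma + Sigma.T) / 2
            for miss_cols, rows in joint["groups"].items():
                mcols = np.array(miss_cols)
                ocols = np.setdiff1d(np.arange(p), mcols)
                if ocols.size:
                    Soo = Sigma[np.ix_(ocols, ocols)]
                    Smo = Sigma[np.ix_(mcols, ocols)]
                    B = Smo @ np.linalg.inv(Soo)
                    cmean = M[mcols] + (X[np.ix_(rows, ocols)] - M[ocols]) @ B.T
                    ccov = Sigma[np.ix_(mcols, mcols)] - B @ Smo.T
                else:
                    cmean = np.tile(M[mcols], (rows.size, 1))
                    ccov = Sigma[np.ix_(mcols, mcols)]
                Lc = np.linalg.cholesky((ccov + ccov.T) / 2 + 1e-12 * np.eye(mcols.size))
                prop = cmean + rng.standard_normal((rows.size, mcols.size)) @ Lc.T
                d_eta = (prop - X[np.ix_(rows, mcols)]) @ beta[mcols]
                # per-row Metropolis with the prior conditional as proposal
                eta_new = eta[rows] + d_eta
                delta = _kernel_rows(lik, eta_new, rows) - _kernel_rows(lik, eta[rows], rows)
                accept = np.log(rng.random(rows.size)) < delta
                if accept.any():
                    sel = rows[accept]
                    X[np.ix_(sel, mcols)] = prop[accept]
                    eta[sel] = eta_new[accept]
        elif joint["mode"] == "car_joint":
            for j, mis in joint["mis_cols"].items():
                col = X[:, j]
                # single-site Gibbs proposal from the ICAR full conditional
                for i in mis:
                    nbr_mean = (W[i] @ col) / m[i]
                    prop = rng.normal(nbr_mean, 1.0 / np.sqrt(tau_v[j] * m[i]))
                    d_eta = (prop - col[i]) * beta[j]
                    delta = _kernel_one(lik, eta[i] + d_eta, i) - _kernel_one(lik, eta[i], i)
                    if np.log(rng.random()) < delta:
                        col[i] = prop
                        eta[i] += d_eta
                quad = float(col @ Q @ col)
                tau_v[j] = rng.gamma(1.0 + 0.5 * (N - 1), 1.0 / (0.01 + 0.5 * quad))

        # --- intercept ---
        prop = alpha + s_alpha * rng.standard_normal()
        d = prop - alpha
        delta = np.sum(lik.kernel(eta + d)) - np.sum(lik.kernel(eta))
        delta += (alpha**2 - prop**2) / (2 * alpha_var)
        if np.log(rng.random()) < delta:
            alpha = prop
            eta = eta + d
            acc_alpha += 1

        # --- coefficients, scalar scans ---
        for j in range(p):
            bj = beta[j]
            prop = bj + s_beta[j] * rng.standard_normal()
            eta_new = eta + (prop - bj) * X[:, j]
            delta = np.sum(lik.kernel(eta_new)) - np.sum(lik.kernel(eta))
            delta += 0.5 * tau_beta[j] * (bj**2 - prop**2)
            if np.log(rng.random()) < delta:
                beta[j] = prop
                eta = eta_new
                acc_beta[j] += 1
            # coefficient scale hyperparameter
            tau_beta[j] = _draw_precision(rng, priors["beta"], priors, beta[j] ** 2, 1)

        # --- joint adaptive update of (alpha, beta): the posterior over the
        # fixed effects is strongly correlated when covariates correlate with
        # each other and with the spatial field, so a correlated proposal
        # learned during burn-in is essential for mixing
        theta = np.concatenate(([alpha], beta))
        adapt.update(theta)
        prop_theta = adapt.propose(rng, theta)
        eta_new = eta + (prop_theta[0] - alpha) + X @ (prop_theta[1:] - beta)
        delta = np.sum(lik.kernel(eta_new)) - np.sum(lik.kernel(eta))
        delta += (alpha**2 - prop_theta[0] ** 2) / (2 * alpha_var)
        delta += 0.5 * np.sum(tau_beta * (beta**2 - prop_theta[1:] ** 2))
        if np.log(rng.random()) < delta:
            alpha = float(prop_theta[0])
            beta = prop_theta[1:].copy()
            eta = eta_new
            adapt.accepted += 1

        # --- ridge moves: trade beta_j against a compensating shift of the
        # spatial (or exchangeable) field. eta is exactly invariant, so only
        # the priors vote; this walks the weakly identified direction created
        # by spatially smooth covariates (spatial confounding) that no
        # single-site update can traverse
        if config.include_random_effects:
            if joint["mode"] != "none" or x_static is None:
                Xc_cols = X - X.mean(axis=0)
                QX = Q @ X
                xQx = np.einsum("ij,ij->j", X, QX)
                if joint["mode"] == "none":
                    x_static = (Xc_cols, QX, xQx)
            else:
                Xc_cols, QX, xQx = x_static
            quad_S = float(S @ Q @ S)
            for j in range(p):
                d = s_ridge[j] * rng.standard_normal()
                # S-compensated: beta_j += d, S -= d * Xc_j, alpha -= d * xbar_j
                quad_new = quad_S - 2 * d * float(S @ QX[:, j]) + d * d * xQx[j]
                bj_new = beta[j] + d
                a_new = alpha - d * X[:, j].mean()
                delta = -0.5 * tau_S * (quad_new - quad_S)
                delta += 0.5 * tau_beta[j] * (beta[j] ** 2 - bj_new**2)
                delta += (alpha**2 - a_new**2) / (2 * alpha_var)
                if np.log(rng.random()) < delta:
                    S = S - d * Xc_cols[:, j]
                    beta[j] = bj_new
                    alpha = a_new
                    quad_S = quad_new
                    acc_ridge[j] += 1
                # U-compensated variant
                d = s_ridge_u[j] * rng.standard_normal()
                u_new = u - d * Xc_cols[:, j]
                bj_new = beta[j] + d
                a_new = alpha - d * X[:, j].mean()
                delta = 0.5 * tau_U * (u @ u - u_new @ u_new)
                delta += 0.5 * tau_beta[j] * (beta[j] ** 2 - bj_new**2)
                delta += (alpha**2 - a_new**2) / (2 * alpha_var)
                if np.log(rng.random()) < delta:
                    u = u_new
                    beta[j] = bj_new
                    alpha = a_new
                    acc_ridge_u[j] += 1

        if config.include_random_effects:
            # --- level swap between the intercept and the exchangeable
            # effects: eta is invariant, only the priors vote, so the move
            # walks along the alpha/mean(U) ridge
            d = 0.5 * rng.standard_normal() / np.sqrt(tau_U * N)
            u_new = u - d
            delta = 0.5 * tau_U * (u @ u - u_new @ u_new)
            delta += (alpha**2 - (alpha + d) ** 2) / (2 * alpha_var)
            if np.log(rng.random()) < delta:
                alpha += d
                u = u_new

            # --- exchangeable effects ---
            prop_u = u + s_u * rng.standard_normal(N)
            eta_new = eta + (prop_u - u)
            delta = lik.kernel(eta_new) - lik.kernel(eta) + 0.5 * tau_U * (u**2 - prop_u**2)
            accept = np.log(rng.random(N)) < delta
            u = np.where(accept, prop_u, u)
            eta = np.where(accept, eta_new, eta)
            acc_u += accept

            tau_U = _draw_precision(rng, priors["sigma_U"], priors, float(u @ u), N)

            # --- spatial effects, colour-blocked ---
            for cls in colors:
                prop_S = S[cls] + s_S[cls] * rng.standard_normal(cls.size)
                eta_new = eta[cls] + (prop_S - S[cls])
                nbr_mean = (W[cls] @ S) / m[cls]
                lp_old = -0.5 * tau_S * m[cls] * (S[cls] - nbr_mean) ** 2
                lp_new = -0.5 * tau_S * m[cls] * (prop_S - nbr_mean) ** 2
                delta = (
                    _kernel_rows(lik, eta_new, cls)
                    - _kernel_rows(lik, eta[cls], cls)
                    + lp_new
                    - lp_old
                )
                accept = np.log(rng.random(cls.size)) < delta
                S[cls] = np.where(accept, prop_S, S[cls])
                eta[cls] = np.where(accept, eta_new, eta[cls])
                acc_S[cls] += accept
            # sum-to-zero recentring; the intercept absorbs the level shift
            shift = S.mean()
            S -= shift
            alpha += shift

            tau_S = _draw_precision(rng, priors["sigma_S"], priors, float(S @ Q @ S), N - 1)

        # --- adaptation during burn-in ---
        if t < config.burnin and (t + 1) % ADAPT_EVERY == 0:
            s_alpha *= np.exp((acc_alpha / ADAPT_EVERY - 0.44))
            s_beta *= np.exp(acc_beta / ADAPT_EVERY - 0.44)
            s_u *= np.exp(acc_u / ADAPT_EVERY - 0.30)
            s_S *= np.exp(acc_S / ADAPT_EVERY - 0.30)
            s_ridge *= np.exp(acc_ridge / ADAPT_EVERY - 0.44)
            s_ridge_u *= np.exp(acc_ridge_u / ADAPT_EVERY - 0.44)
            s_alpha = float(np.clip(s_alpha, 1e-5, 10.0))
            s_beta = np.clip(s_beta, 1e-5, 10.0)
            s_u = np.clip(s_u, 1e-5, 10.0)
            s_S = np.clip(s_S, 1e-5, 10.0)
            s_ridge = np.clip(s_ridge, 1e-5, 10.0)
            s_ridge_u = np.clip(s_ridge_u, 1e-5, 10.0)
            acc_alpha = 0
            acc_beta[:] = 0
            acc_u[:] = 0
            acc_S[:] = 0
            acc_ridge[:] = 0
            acc_ridge_u[:] = 0

        if t >= config.burnin:
            k = t - config.burnin
            store["alpha"][k] = alpha
            store["beta"][k] = beta
            store["sigma_U2"][k] = 1.0 / tau_U
            store["sigma_S2"][k] = 1.0 / tau_S
            store["U"][k] = u
            store["S"][k] = S
            store["eta"][k] = eta
            store["deviance"][k] = lik.deviance(eta)
            store["X_missing_sum"] += np.where(mask, X, 0.0)

    store["X_missing_mean"] = store["X_missing_sum"] / kept
    return store


def _kernel_rows(lik: _Likelihood, eta_rows: np.ndarray, rows: np.ndarray) -> np.ndarray:
    if lik.family == "poisson":
        ll = lik.Y[rows] * eta_rows - lik.E[rows] * np.exp(eta_rows)
    else:
        ll = lik.Y[rows] * eta_rows - lik.n[rows] * np.logaddexp(0.0, eta_rows)
    return lik.w[rows] * ll


def _kernel_one(lik: _Likelihood, eta_i: float, i: int) -> float:
    if lik.w[i] == 0:
        return 0.0
    if lik.family == "poisson":
        return lik.Y[i] * eta_i - lik.E[i] * np.exp(eta_i)
    return lik.Y[i] * eta_i - lik.n[i] * np.logaddexp(0.0, eta_i)


# ---------------------------------------------------------------------------
# public fit


def fit_spatial_glmm(data: RegionDataset, config: "ModelConfig | None" = None) -> PosteriorSummary:
    """Fit the spatial GLMM and summarise the posterior.

    Steps: centre covariates (unless already centred), derive expected
    counts for the Poisson family, complete or jointly model missing
    covariates according to ``config.imputation``, run ``config.chains``
    MCMC chains, pool post-burn-in draws, and report posterior summaries,
    per-region relative risk (RR) and relative excess risk (RER), DIC, and
    split-R-hat convergence diagnostics (warning above 1.05).
    """
    config = config or ModelConfig()
    if data.lattice is None and config.include_random_effects:
        raise DataValidationError("fitting requires a dataset with a lattice")
    work = data.copy()
    if not work.centered.any():
        which = config.center
        work = center_covariates(work, which)
    if config.family == "poisson" and work.E is None:
        work = with_expected_counts(work)

    if config.imputation == "none":
        if work.mask.any():
            raise DataValidationError("imputation='none' requires complete covariates")
    elif config.imputation == "mean":
        work = impute_mean(work).completed

    joint = _prepare_joint_imputation(work, config.imputation)
    priors = resolve_priors(config.prior_model, config.halfnormal_is_variance)
    y_obs = ~np.isnan(work.Y)
    lik = _Likelihood(config.family, work.Y, work.n, work.E if work.E is not None else np.ones(work.n_regions), y_obs)

    chains = []
    for c in range(config.chains):
        seed = np.random.SeedSequence([int(config.seed), 9_001, c])
        chains.append(_run_chain(work, config, priors, seed, lik, joint))

    return _summarise(work, config, lik, chains)


def _summarise(work, config, lik, chains) -> PosteriorSummary:
    import arviz as az

    p = work.n_covariates
    pool = lambda key: np.concatenate([ch[key] for ch in chains], axis=0)
    alpha_d = pool("alpha")
    beta_d = pool("beta")
    sU2 = pool("sigma_U2")
    sS2 = pool("sigma_S2")
    U_d = pool("U")
    S_d = pool("S")
    eta_d = pool("eta")
    dev_d = pool("deviance")

    # plug-in deviance at posterior means of all continuous parameters
    Xbar = work.X.copy()
    if work.mask.any() and config.imputation in ("mvn_joint", "car_joint"):
        Xmm = np.mean([ch["X_missing_mean"] for ch in chains], axis=0)
        Xbar[work.mask] = Xmm[work.mask]
    eta_bar = alpha_d.mean() + Xbar @ beta_d.mean(axis=0) + U_d.mean(axis=0) + S_d.mean(axis=0)
    dic = compute_dic(dev_d, lik.deviance(eta_bar))

    if config.family == "poisson":
        rr_draws = np.exp(eta_d)
    else:
        prob = expit(eta_d)
        pbar = (prob * work.n).sum(axis=1) / work.n.sum()
        rr_draws = prob / pbar[:, None]
    RR = _risk_frame(rr_draws, work.region_ids)
    RER = relative_excess_risk(U_d, S_d, work.region_ids)

    rhat = {}
    warnings = []
    if config.chains >= 2:
        with np.errstate(invalid="ignore", divide="ignore"):
            rhat["alpha"] = float(az.rhat(np.stack([ch["alpha"] for ch in chains])))
            for j, name in enumerate(work.covariate_names):
                rhat[f"beta[{name}]"] = float(
                    az.rhat(np.stack([ch["beta"][:, j] for ch in chains]))
                )
            rhat["sigma_U2"] = float(az.rhat(np.stack([ch["sigma_U2"] for ch in chains])))
            rhat["sigma_S2"] = float(az.rhat(np.stack([ch["sigma_S2"] for ch in chains])))
        bad = {k: v for k, v in rhat.items() if np.isfinite(v) and v > RHAT_WARN}
        if bad:
            warnings.append(f"split-R-hat above {RHAT_WARN}: {bad}")

    beta_summ = tuple(ParamSummary.from_draws(beta_d[:, j]) for j in range(p))
    sig = significance_flags(
        np.array([b.lo for b in beta_summ]), np.array([b.hi for b in beta_summ])
    )
    return PosteriorSummary(
        family=config.family,
        prior_model=config.prior_model,
        covariate_names=work.covariate_names,
        region_ids=work.region_ids,
        alpha=ParamSummary.from_draws(alpha_d),
        beta=beta_summ,
        sigma_S2=ParamSummary.from_draws(sS2),
        sigma_U2=ParamSummary.from_draws(sU2),
        RR=RR,
        RER=RER,
        dic=dic,
        rhat=rhat,
        significant=sig,
        draws={
            "alpha": alpha_d,
            "beta": beta_d,
            "sigma_U2": sU2,
            "sigma_S2": sS2,
            "U": U_d,
            "S": S_d,
            "deviance": dev_d,
        },
        warnings=warnings,
    )
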