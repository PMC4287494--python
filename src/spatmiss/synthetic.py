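"""Synthetic areal datasets with the structure the spatial analysis assumes.

The generator emulates a state-wide disease-prevalence study over ~71
administrative regions: seven correlated lifestyle/demographic covariates
(an ordinal 1-10 socio-economic score and six proportions), spatially
autocorrelated fields, case counts from a Binomial or Poisson GLMM with
both exchangeable and intrinsic-CAR random effects, and a block-structured
missingness mechanism in which small-population regions lose all survey
covariates at once (survey cells are suppressed when the regional sample is
too small to report).

Every sampler is a pure function of its inputs and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import expit, logit

from .data_io import COVARIATE_NAMES, DataValidationError, RegionDataset, RegionLattice

#: Default generating coefficients: a strong negative socio-economic effect,
#: the remaining covariates essentially null (on the centred covariate scale).
DEFAULT_BETA = (-0.18, 0.009, -0.005, 0.007, -0.006, -0.014, -0.005)

#: Observed-scale covariate means and standard deviations the generator
#: targets: SES decile score, then six proportions (over-45, overweight/obese,
#: daily smokers, insufficient activity, adequate fruit, adequate vegetables).
COVARIATE_MOMENTS = {
    "ses": (3.8, 1.8),
    "over45": (0.35, 0.08),
    "overweight": (0.62, 0.06),
    "smokers": (0.19, 0.05),
    "inactive": (0.49, 0.07),
    "fruit": (0.54, 0.05),
    "veg": (0.12, 0.04),
}

#: Single-factor loadings used to build the default covariate correlation
#: matrix (corr = L L' + diag(1 - L^2)): lifestyle covariates share a latent
#: deprivation axis, so many pairs correlate beyond |r| = 0.2.
_DEFAULT_LOADINGS = np.array([-0.50, 0.20, 0.55, 0.50, 0.55, -0.45, -0.45])


def default_covariate_corr() -> np.ndarray:
    """Default 7x7 covariate correlation matrix (single-factor structure)."""
    lam = _DEFAULT_LOADINGS
    C = np.outer(lam, lam)
    np.fill_diagonal(C, 1.0)
    return C


@dataclass
class SyntheticTruth:
    """Generating parameters and realised random effects of one simulation."""

    alpha: float
    beta: np.ndarray
    sigma_U: float
    sigma_S: float
    family: str = "poisson"
    seed: int = 0
    baseline_prev: float = 0.08
    U: "np.ndarray | None" = None
    S: "np.ndarray | None" = None

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.family not in ("binomial", "poisson"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.sigma_U < 0 or self.sigma_S < 0:
            raise ValueError("random-effect standard deviations must be >= 0")
        if self.S is not None and abs(np.sum(self.S)) > 1e-8:
            raise ValueError("spatial field S must sum to zero")

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "beta": self.beta.tolist(),
            "sigma_U": self.sigma_U,
            "sigma_S": self.sigma_S,
            "family": self.family,
            "seed": self.seed,
            "baseline_prev": self.baseline_prev,
            "U": None if self.U is None else np.asarray(self.U).tolist(),
            "S": None if self.S is None else np.asarray(self.S).tolist(),
        }


def default_truth(family: str = "poisson", seed: int = 0, **overrides) -> SyntheticTruth:
    """Study-condition generating truth: strong SES signal, modest residual
    spatial and exchangeable variation (sd 0.11 and 0.25 on the log scale)."""
    params = dict(
        alpha=0.0,
        beta=np.array(DEFAULT_BETA),
        sigma_U=0.25,
        sigma_S=0.11,
        family=family,
        seed=seed,
        baseline_prev=0.08,
    )
    params.update(overrides)
    return SyntheticTruth(**params)


# ---------------------------------------------------------------------------
# lattices


def make_grid_lattice(rows: int, cols: int) -> RegionLattice:
    """Rook-adjacency grid lattice with ``rows x cols`` regions.

    Region ids are ``r{i}c{j}`` in row-major order. Any shape with at least
    two regions is accepted (a 1xk grid is a chain with end regions having a
    single neighbour).
    """
    if rows < 1 or cols < 1 or rows * cols < 2:
        raise DataValidationError("grid needs at least 2 regions")
    ids = [f"r{i}c{j}" for i in range(rows) for j in range(cols)]
    edges = []
    for i in range(rows):
        for j in range(cols):
            if j + 1 < cols:
                edges.append((f"r{i}c{j}", f"r{i}c{j+1}"))
            if i + 1 < rows:
                edges.append((f"r{i}c{j}", f"r{i+1}c{j}"))
    return RegionLattice.from_edges(ids, edges)


def make_study_lattice(n_regions: int = 71) -> RegionLattice:
    """Connected rook lattice with an odd region count, at the case-study scale.

    Builds the smallest grid with at least ``n_regions`` cells and trims
    trailing cells from the last row (keeping connectivity), giving an
    irregular boundary like a real administrative map.
    """
    import math

    cols = max(2, int(math.ceil(math.sqrt(n_regions))))
    rows = int(math.ceil(n_regions / cols))
    full = [(i, j) for i in range(rows) for j in range(cols)]
    keep = full[:n_regions]
    ids = [f"r{i}c{j}" for i, j in keep]
    keep_set = set(keep)
    edges = []
    for i, j in keep:
        if (i, j + 1) in keep_set:
            edges.append((f"r{i}c{j}", f"r{i}c{j+1}"))
        if (i + 1, j) in keep_set:
            edges.append((f"r{i}c{j}", f"r{i+1}c{j}"))
    return RegionLattice.from_edges(ids, edges)


# ---------------------------------------------------------------------------
# intrinsic CAR field sampling


def _icar_eigenbasis(lattice: RegionLattice) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of Q = diag(m) - W with the null space dropped.

    Returns (eigenvalues, eigenvectors) of the positive part. On a connected
    lattice the null space is exactly span(1), so the retained eigenvectors
    span the sum-to-zero subspace.
    """
    Q = lattice.icar_precision()
    vals, vecs = np.linalg.eigh(Q)
    tol = 1e-9 * max(1.0, vals[-1])
    null_count = int(np.sum(vals < tol))
    if null_count != 1:
        raise DataValidationError(
            "lattice is disconnected: intrinsic CAR fields need a connected map"
        )
    return vals[1:], vecs[:, 1:]


def sample_car_field(
    lattice: RegionLattice,
    sigma_S: float,
    seed: "int | np.random.Generator" = 0,
    size: "int | None" = None,
) -> np.ndarray:
    """Draw from the intrinsic CAR distribution on the sum-to-zero subspace.

    The intrinsic CAR prior has (improper) precision ``(1/sigma_S^2) *
    (diag(m) - W)``; a draw is realised as a proper Gaussian on the
    sum-to-zero subspace via the eigendecomposition of ``diag(m) - W``,
    so its covariance is ``sigma_S^2`` times the Moore-Penrose pseudo-inverse
    of that matrix. ``sigma_S`` is the conditional standard deviation scale:
    conditionally, ``S_i | S_-i ~ N(mean of neighbours, sigma_S^2 / m_i)``.

    Returns an array of shape ``(n_regions,)`` or ``(size, n_regions)``.
    Every draw sums to zero.
    """
    if sigma_S < 0:
        raise ValueError("sigma_S must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = lattice.n_regions
    shape = (n,) if size is None else (size, n)
    if sigma_S == 0:
        return np.zeros(shape)
    vals, vecs = _icar_eigenbasis(lattice)
    k = (n - 1,) if size is None else (size, n - 1)
    z = rng.standard_normal(k) / np.sqrt(vals)
    S = sigma_S * z @ vecs.T
    # enforce the constraint exactly against eigenvector round-off
    S -= S.mean(axis=-1, keepdims=True)
    return S


# ---------------------------------------------------------------------------
# full dataset simulation


def simulate_dataset(
    lattice: RegionLattice,
    truth: SyntheticTruth,
    covariate_corr: "np.ndarray | None" = None,
    covariate_spatial_sd: float = 1.0,
    population_range: tuple = (1_000, 1_000_000),
    seed: "int | None" = None,
) -> tuple[RegionDataset, SyntheticTruth]:
    """Simulate a complete region dataset from the GLMM generative model.

    Covariates are built on a latent Gaussian scale as a cross-correlated
    draw (Cholesky of ``covariate_corr``) plus an independent intrinsic CAR
    component per covariate scaled by ``covariate_spatial_sd`` (in latent sd
    units, so spatial share = c^2 / (1 + c^2)); the SES column is then
    discretised to the 1-10 decile scale and proportion columns pass through
    a logit transform so they stay in (0, 1). Populations are log-uniform
    over ``population_range``. Outcomes follow

    * binomial: ``Y_i ~ Bin(n_i, expit(eta_i))``,
    * poisson:  ``Y_i ~ Pois(E_i exp(eta_i))`` with ``E_i = prev0 * n_i``,

    where ``eta_i = alpha_adj + x_i beta + U_i + S_i`` and the linear
    predictor centres every covariate about its realised mean, so
    ``truth.alpha`` is the baseline level of a typical region relative to
    ``baseline_prev`` (poisson) or on the logit scale shifted by
    ``logit(baseline_prev)`` (binomial).

    Returns the complete dataset (no missingness; apply
    :func:`apply_missingness` separately) and the truth with realised
    ``U`` and ``S`` filled in.
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    n = lattice.n_regions
    p = len(COVARIATE_NAMES)
    if covariate_corr is None:
        covariate_corr = default_covariate_corr()
    covariate_corr = np.asarray(covariate_corr, dtype=float)
    eigmin = float(np.linalg.eigvalsh(covariate_corr).min())
    if eigmin <= 1e-10:
        raise DataValidationError(
            f"covariate correlation matrix is not positive definite (min eigenvalue {eigmin:.3g})"
        )
    lo, hi = population_range
    if lo <= 0 or hi < lo:
        raise DataValidationError("population_range must be positive with lo <= hi")

    # latent standard-normal covariate scores: cross-correlated + spatial
    L = np.linalg.cholesky(covariate_corr)
    G = rng.standard_normal((n, p)) @ L.T
    c = float(covariate_spatial_sd)
    if c > 0:
        fields = sample_car_field(lattice, 1.0, rng, size=p).T  # (n, p)
        sd = fields.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        # correlate the spatial components with the same Cholesky factor so
        # the latent cross-covariate correlation equals covariate_corr
        fields = (fields / sd) @ L.T
        Z = (G + c * fields) / np.sqrt(1.0 + c * c)
    else:
        Z = G

    X = np.empty((n, p))
    for j, name in enumerate(COVARIATE_NAMES):
        mu, s = COVARIATE_MOMENTS[name]
        if name == "ses":
            X[:, j] = np.clip(np.round(mu + s * Z[:, j]), 1, 10)
        else:
            # delta-method match of mean/sd on the logit scale
            loc = logit(mu)
            scale = s / (mu * (1.0 - mu))
            X[:, j] = expit(loc + scale * Z[:, j])

    pop = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n)).astype(int)
    pop = np.maximum(pop, 1)

    U = rng.normal(0.0, truth.sigma_U, size=n) if truth.sigma_U > 0 else np.zeros(n)
    S = sample_car_field(lattice, truth.sigma_S, rng)

    Xc = X - X.mean(axis=0)
    eta = truth.alpha + Xc @ truth.beta + U + S
    if truth.family == "binomial":
        prob = expit(logit(truth.baseline_prev) + eta)
        Y = rng.binomial(pop, prob).astype(float)
    else:
        E = truth.baseline_prev * pop
        Y = rng.poisson(E * np.exp(eta)).astype(float)

    data = RegionDataset(
        region_ids=lattice.region_ids,
        Y=Y,
        n=pop,
        X=X,
        mask=np.zeros((n, p), dtype=bool),
        covariate_names=COVARIATE_NAMES,
        lattice=lattice,
    )
    out_truth = replace(truth, U=U, S=S)
    return data, out_truth


# ---------------------------------------------------------------------------
# missingness mechanisms

#: Covariates suppressed together by the small-sample survey rule.
SURVEY_COVARIATES = ("over45", "overweight", "smokers", "inactive", "fruit", "veg")


def apply_missingness(
    data: RegionDataset,
    mechanism: str = "suppressed_block",
    params: "dict | None" = None,
    seed: int = 0,
) -> RegionDataset:
    """Mask covariate (and optionally outcome) cells.

    ``mcar`` masks each cell of the selected covariates independently with
    probability ``fraction``. ``suppressed_block`` emulates survey-cell
    suppression: regions are ranked by population and the lowest-population
    ``fraction`` of them lose all six survey covariates at once; a further
    ``extra_fraction`` of the next-smallest regions lose one designated
    covariate (default ``veg``, the one with the weakest survey coverage);
    optionally the ``n_missing_y`` smallest regions also lose the outcome.

    Defaults mirror the study pattern on 71 regions: 28/71 (39%) of regions
    lose the survey block, 32/71 (45%) lose the vegetable-intake covariate,
    and 4 small regions lack the outcome.
    """
    params = dict(params or {})
    out = data.copy()
    if mechanism == "mcar":
        fraction = float(params.pop("fraction", 0.3))
        names = params.pop("covariates", SURVEY_COVARIATES)
        if params:
            raise ValueError(f"unknown mcar params {sorted(params)}")
        if not 0.0 <= fraction <= 1.0:
            raise ValueError("mcar fraction must be in [0, 1]")
        rng = np.random.default_rng(seed)
        cols = [out.covariate_index(nm) for nm in names]
        hit = rng.random((out.n_regions, len(cols))) < fraction
        for jj, j in enumerate(cols):
            out.mask[hit[:, jj], j] = True
    elif mechanism == "suppressed_block":
        fraction = float(params.pop("fraction", 28 / 71))
        extra_fraction = float(params.pop("extra_fraction", 4 / 71))
        extra_covariate = params.pop("extra_covariate", "veg")
        n_missing_y = int(params.pop("n_missing_y", 0))
        if params:
            raise ValueError(f"unknown suppressed_block params {sorted(params)}")
        if not 0.0 <= fraction <= 1.0 or not 0.0 <= extra_fraction <= 1.0:
            raise ValueError("fractions must be in [0, 1]")
        order = np.argsort(out.n, kind="stable")  # ascending population
        n_block = int(round(fraction * out.n_regions))
        n_extra = int(round(extra_fraction * out.n_regions))
        block = order[:n_block]
        cols = [out.covariate_index(nm) for nm in SURVEY_COVARIATES if nm in out.covariate_names]
        for j in cols:
            out.mask[block, j] = True
        if n_extra > 0 and extra_covariate in out.covariate_names:
            j = out.covariate_index(extra_covariate)
            out.mask[order[n_block : n_block + n_extra], j] = True
        if n_missing_y > 0:
            out.Y[order[:n_missing_y]] = np.nan
    else:
        raise ValueError(f"unknown missingness mechanism {mechanism!r}")
    out.X[out.mask] = np.nan
    return out


def benchmark_scenario(kind: str, seed: int = 0, n_regions: int = 71):
    """Datasets in which a known imputation method should win cross-validation.

    * ``"noise"`` — independent, spatially unstructured covariates: no
      information to borrow, so the observed column mean is the best
      predictor of a masked cell.
    * ``"spatial"`` — strongly spatially autocorrelated covariates (latent
      spatial sd 3, ~90% spatial variance share) with light MCAR
      missingness: neighbours carry most of the signal, favouring the CAR
      method.
    * ``"correlated"`` — strongly cross-correlated covariates (single
      factor, loadings 0.95) with no spatial structure and light MCAR
      missingness: the fully observed SES column predicts the masked survey
      cells, favouring the multivariate-normal method.
    """
    lattice = make_study_lattice(n_regions)
    truth = default_truth(seed=seed)
    if kind == "noise":
        data, _ = simulate_dataset(
            lattice, truth, covariate_corr=np.eye(7), covariate_spatial_sd=0.0, seed=seed
        )
        return apply_missingness(data, "mcar", {"fraction": 0.15}, seed=seed)
    if kind == "spatial":
        data, _ = simulate_dataset(
            lattice, truth, covariate_corr=np.eye(7), covariate_spatial_sd=3.0, seed=seed
        )
        return apply_missingness(data, "mcar", {"fraction": 0.15}, seed=seed)
    if kind == "correlated":
        lam = np.full(7, 0.95)
        corr = np.outer(lam, lam)
        np.fill_diagonal(corr, 1.0)
        data, _ = simulate_dataset(
            lattice, truth, covariate_corr=corr, covariate_spatial_sd=0.0, seed=seed
        )
        return apply_missingness(data, "mcar", {"fraction": 0.15}, seed=seed)
    raise ValueError(f"unknown scenario {kind!r}")


def make_study_dataset(
    seed: int = 0,
    family: str = "poisson",
    n_regions: int = 71,
    missingness: bool = True,
    truth: "SyntheticTruth | None" = None,
    **simulate_kwargs,
) -> tuple[RegionDataset, SyntheticTruth]:
    """One-call generator at the study's conditions.

    71 regions on an irregular rook lattice, correlated covariates with a
    spatial component, GLMM outcomes with a strong socio-economic signal,
    and (by default) block-suppressed survey covariates in the 28
    lowest-population regions, vegetable intake suppressed in 4 more, and
    the outcome missing for the 4 smallest regions.
    """
    lattice = make_study_lattice(n_regions)
    if truth is None:
        truth = default_truth(family=family, seed=seed)
    data, truth = simulate_dataset(lattice, truth, seed=seed, **simulate_kwargs)
    if missingness:
        data = apply_missingness(
            data,
            "suppressed_block",
            {"fraction": 28 / 71, "extra_fraction": 4 / 71, "n_missing_y": 4},
            seed=seed,
        )
    return data, truth
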