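# Methods

`spatmiss` implements a complete Bayesian workflow for areal (lattice)
disease-risk analysis with substantially missing covariate data: spatial
generalised linear mixed models with intrinsic CAR random effects, three
competing missing-covariate imputation strategies, a cross-validation
framework for choosing among them, and downstream sensitivity and
mediation screens. This note records the models, their assumptions, the
numerical choices, and what the synthetic-data generator does and does not
emulate.

## The spatial model

For region $i = 1, \dots, N$ with observed case count $Y_i$, population
$n_i$ and covariate row $x_i$:

* **Binomial**: $Y_i \sim \mathrm{Bin}(n_i, p_i)$ with
  $\mathrm{logit}(p_i) = \alpha + x_i \beta + U_i + S_i$;
* **Poisson**: $Y_i \sim \mathrm{Pois}(E_i \lambda_i)$ with
  $\log \lambda_i = \alpha + x_i \beta + U_i + S_i$.

Expected counts use internal standardisation: $E_i = \bar p \, n_i$ where
$\bar p$ is total observed cases over the population of regions with an
observed count. This makes $\lambda_i$ a relative risk (RR) that averages
about 1, and ties $\sum E_i = \sum Y_i$ over observed regions exactly.

$U_i \sim N(0, \sigma_U^2)$ is an exchangeable residual;
$S$ carries the intrinsic CAR (Besag) prior with conditional form
$S_i \mid S_{-i} \sim N(\bar S_{\partial i}, \sigma_S^2 / m_i)$, where
$\partial i$ are the $m_i$ adjacent regions. The joint ICAR density has
precision $(1/\sigma_S^2)(\mathrm{diag}(m) - W)$, which is singular; we
identify $S$ with a sum-to-zero constraint and let the intercept carry the
level. Regions without neighbours (islands) are rejected at data load: a
CAR model has nothing to smooth them against.

The **relative excess risk** is $RER_i = \exp(U_i + S_i)$ per posterior
draw: the multiplicative risk left unexplained after the covariate effects;
$RER_i = 1$ means the covariates fully account for the region's risk.

Regions with a missing outcome contribute no likelihood but keep their
random effects and covariates, so they receive RR/RER predictions
(posterior-predictive smoothing). Coefficients are declared *significant*
when the central 95% credible interval excludes zero (strictly: an interval
touching zero does not count).

### Priors (sensitivity grid)

Five configurations, written in the precision notation of the BUGS
modelling languages, where $N(0, 0.01)$ means variance 100:

| component | model 1 (baseline) | model 2 | model 3 | model 4 | model 5 |
|---|---|---|---|---|---|
| $\alpha$ | $N(0, \tau{=}0.01)$ | same | same | same | same |
| $\beta_j$ | $N(0, 1/\tau_{\beta_j})$, $\tau \sim \mathrm{Ga}(1, 0.01)$ | same | $\sigma_{\beta_j} \sim U(0.01, 5)$ | as 1 | as 1 |
| $\sigma_U$ | $\tau_U \sim \mathrm{Ga}(1, 0.01)$ | same | $U(0.01, 5)$ | half-normal | log-normal |
| $\sigma_S$ | $\tau_S \sim \mathrm{Ga}(1, 0.01)$ | same | $U(0.01, 5)$ | as 1 | as 1 |

Two deliberate interpretation choices, both exposed as configuration:

* The half-normal prior scale 0.0625 is read as a **variance** (sd 0.25)
  by default; `halfnormal_is_variance=False` reads it as a precision
  (sd 4). The source notation is ambiguous between the two conventions.
* The log-normal prior for $\sigma_U$ reads $\log \sigma_U \sim N(0, 4)$
  with 4 as a variance, for consistency with the half-normal default.
* A "CAR prior on $\beta$" appears in some presentations of the baseline
  configuration; a CAR structure indexed over covariates has no adjacency
  to smooth over, so models 1 and 2 here share the independent
  normal-with-Gamma-precision coefficient prior, and the baseline's CAR
  machinery applies to the covariate *data* (the `car_joint` imputation
  mode) rather than to the coefficients.

### Sampler

Metropolis-within-Gibbs, designed so every update is either conjugate or a
cheap vectorised random walk:

* $\alpha$ and each $\beta_j$: adaptive scalar random walks *plus* one
  joint multivariate-normal proposal per iteration whose covariance is
  learned from the burn-in history (Haario-style, frozen afterwards).
* $U$: all regions proposed at once; accept/reject independently (their
  full conditionals are independent given the rest).
* $S$: the lattice is greedily coloured; regions of one colour have
  conditionally independent ICAR full conditionals and are updated as a
  vector, colour by colour. After the scan $S$ is recentred to sum to zero
  and the level moves into $\alpha$ (the ICAR prior is level-invariant, so
  the recentring is exact, not approximate).
* **Ridge moves**: spatially smooth covariates create a weakly identified
  direction — a shift of $\beta_j$ can be absorbed by an opposite shift of
  the spatial field (spatial confounding). Single-site updates cannot walk
  this ridge, and without help the chains stall and understate $\beta$.
  We add likelihood-invariant proposals
  $(\beta_j, S, \alpha) \to (\beta_j + \delta,\; S - \delta \tilde x_j,\; \alpha - \delta \bar x_j)$
  (and an analogous $U$-compensated variant), where $\tilde x_j$ is the
  centred covariate. The linear predictor is unchanged, so only the priors
  enter the acceptance ratio. A similar zero-cost "level swap" walks the
  $\alpha$-versus-$\mathrm{mean}(U)$ ridge.
* Precisions with Gamma priors are conjugate
  ($\tau_S$ uses the quadratic form $S^\top(\mathrm{diag}(m)-W)S$ with
  $N-1$ effective terms). Bounded-uniform, half-normal and log-normal
  standard deviations are drawn by inverse-CDF on a fixed 400-point grid
  (linear on $[0.01, 5]$ for the uniform, log-spaced otherwise) — exact up
  to grid resolution and unconditionally stable.
* Convergence is summarised by split-$\hat R$ (via ArviZ) over $\ge 2$
  chains; values above 1.05 on any of $\alpha$, $\beta$, or the variance
  components are recorded as warnings in the posterior summary.

Defaults are 4,000 iterations with 2,000 burn-in and 2 chains — desk-scale
settings at which a 71-region fit takes seconds; production chains of
100,000/50,000 are a configuration change, not a code change.

DIC follows the classic decomposition: $\bar D$ is the posterior mean
deviance (full log-likelihood, constants included), $p_D = \bar D -
D(\bar\theta)$ with the plug-in deviance evaluated at the posterior means
of all continuous parameters (including jointly imputed covariate cells),
and $\mathrm{DIC} = \bar D + p_D$.

## Imputation methods

All three leave observed cells bit-identical and report per-cell point
estimates and central 95% credible intervals.

**Mean** — each missing cell takes its covariate's observed mean.
Deterministic; zero relative bias by construction; deflates the completed
column's sd (the completed mean equals the observed mean exactly).

**Multivariate normal (MVN)** — rows $x_i \sim \mathrm{MVN}(M, \Sigma)$,
flat prior on $M$ (the vague limit of a normal prior), and
$\Sigma^{-1} \sim \mathrm{Wishart}(\psi, \nu)$ in the rate convention (the
posterior update is $\psi \to \psi + \mathrm{SSE}$), with $\psi$ built
directly from the stated inverse variances 0.01 (diagonal) and inverse
covariances 0.001 (off-diagonal). $\nu$ defaults to $p = 7$, the weakest
proper choice, and is exposed as a parameter. The Gibbs scan draws
$M \mid \Sigma$, $\Sigma^{-1} \mid M$, then each missing cell from the
exact Gaussian conditional given the observed cells of its row (rows
grouped by missingness pattern for speed). With block missingness the only
observed predictor in a suppressed row is the SES column — precisely why
strong cross-correlation is required for this method to pay off.

**CAR** — one independent intrinsic CAR model per covariate: the covariate
surface itself carries the ICAR prior with conditional variance
$\sigma_{vj}^2 / m_i$, its precision has a Gamma(1, 0.01) prior, and the
spatial variance is estimated per covariate (each covariate gets its own
degree of smoothness). Because the ICAR density is invariant to level
shifts and the observed cells are conditioned on exactly, the conditional
distribution of the missing cells is a proper Gaussian and no explicit
intercept is needed — this is the same identification as
"intercept + sum-to-zero field", realised conditionally. The conditional
mean of the missing block is constant across iterations (it does not
depend on $\sigma_v$), so the Gibbs sampler mixes essentially instantly;
cells whose entire neighbourhood is missing are flagged
`prior_dominated`, and their intervals are honest about it (wide).

Joint ("model-embedded") variants `mvn_joint` and `car_joint` sample the
missing cells inside the GLMM: the proposal is the prior full conditional
(row-conditional MVN, or single-site ICAR conditional), so the Metropolis
correction is just the outcome-likelihood ratio. Regions with imputed
covariates therefore show wider RR intervals than under plug-in mean
imputation — uncertainty propagates instead of being hidden.

## Cross-validation of imputation methods

Only regions with fully observed covariates enter the rotation (39 of 71
under the default missingness pattern). Each of 10 rounds draws 10% of
them (4 regions) as a test set, masks their six survey covariates
*jointly* — reproducing the block structure of real suppression, with the
always-observed SES column left available as a predictor — re-imputes with
each method, and scores each masked cell:

* error $\hat x_{ij} - x_{ij}$; per-covariate RMSE per round, then mean and
  sd across rounds;
* relative bias $(\hat x_{ij} - \bar x_j) / \bar x_j$ with $\bar x_j$ the
  mean of *training* observations (test truth must not leak); the mean
  method's bias is identically zero;
* the 95% interval width, and whether the interval covers zero bias
  (equivalently, contains $\bar x_j$). The mean method's degenerate
  interval sits exactly at zero bias, so its coverage is 100% by
  construction.

Overall figures weight covariates equally (not by cell count); the
alternative cell-weighted overall and a pooled-cells RMSE variant sit
behind flags (`weight_by_cells`, `pool_cells`), defaults off. Overall bias
averages signed per-covariate biases. Selection: smallest overall RMSE,
ties by smallest |overall bias|, then lexicographic; the decision inputs
are all in the returned report.

Per-round seeds derive deterministically from (base seed, round), so any
round can be reproduced in isolation.

## Sensitivity and mediation

The prior grid refits the model for every (prior model, family) cell from
a shared seed and tabulates coefficients, residual variances and DIC; a
failed cell is recorded and the grid continues. No automatic DIC winner is
declared — the table is for inspection.

The mediation screen is a coefficient-change heuristic, not a causal
estimand: fit the univariate exposure model, then add one candidate at a
time; flag the candidate if the exposure coefficient moves by strictly
more than 10% (10.0% exactly is not flagged). Candidates are fit on
mean-imputed data by default, mirroring the sequencing of
selection-then-inference. If the univariate coefficient is numerically
near zero (<1e-6) the percentage change is undefined and reported unset.

## The synthetic-data generator

The generator reproduces the statistical regime of a state-wide
prevalence study over ~71 local government areas, because the original
administrative inputs are not redistributable:

* an irregular rook lattice of 71 regions (a trimmed grid — irregular
  boundary, no islands, connected);
* seven covariates built on a latent Gaussian scale: a single-factor
  cross-correlation structure (defaults produce roughly half the pairs
  with |r| > 0.2) plus an intrinsic-CAR spatial component per covariate
  (default spatial share 50%); the SES column is discretised to the 1–10
  decile scale and the six proportions pass through a logit transform, with
  means and sds targeted at observed survey descriptives (e.g. overweight
  0.62 ± 0.06, vegetables 0.12 ± 0.04, SES 3.8 ± 1.8);
* log-uniform populations over (10³, 10⁶) — the population distribution of
  real administrative regions is heavy-tailed and this is a deliberate,
  configurable stand-in;
* outcomes drawn from the GLMM itself, with default truth: SES coefficient
  −0.18 per decile, the other six coefficients near zero,
  $\sigma_U = 0.25$, $\sigma_S = 0.11$, baseline prevalence 8%;
* block missingness: regions ranked by population; the smallest 28/71
  (39%) lose all six survey covariates simultaneously, 4 more lose only
  vegetable intake (32/71 = 45% total for that covariate), and the 4
  smallest regions also lack the outcome — leaving 39 fully observed
  regions. Missingness is monotone in population, i.e. *not at random*.

Three named `benchmark_scenario`s isolate one information channel each
(pure noise / spatial / cross-correlated, all with 15% MCAR base
missingness) so the cross-validation harness can be shown to select mean,
CAR and MVN respectively. In the noise scenario the margin between mean
and the stochastic methods is structurally small (they all converge on the
column mean); the directional claim holds for typical seeds but individual
seeds can tie.

What the generator does **not** emulate: real geography or adjacency
graphs, survey design effects (the age/gender weighting upstream of
published survey estimates), measurement bias in disease notifications,
and any covariate missingness mechanism other than the suppression rule
and MCAR. Passing tests therefore demonstrate correctness of the machinery
under the stated generative regime, not robustness to those real-world
features.

## Numerical details and edge cases

* Missing cells are `nan` plus an explicit boolean mask, validated to
  agree; no sentinel values.
* Adjacency files: plain edge lists (symmetric closure applied) or
  GAL-style neighbour files; labels are resolved against the region
  table's order, which is canonical.
* Centring: the six survey/age covariates are centred on their observed
  means by default; the ordinal SES score is not (a flag includes it).
  Centring is exactly idempotent (already-centred columns are skipped) and
  stores offsets for back-transformation.
* Pearson screening uses pairwise-complete deletion; pairs with fewer than
  3 complete observations are reported unset.
* CSV round-trips are bit-exact (`%.17g` on write, round-trip float
  parsing on read).
* CAR sampling uses the eigendecomposition of $\mathrm{diag}(m) - W$ with
  the null eigenvector dropped; a disconnected lattice is an error rather
  than a silent per-component constraint.
* Seeds: every stochastic routine takes an explicit seed and derives
  sub-streams via `SeedSequence`, so chains, rounds and covariates are
  independently reproducible; identical seeds give bit-identical output.

## Known limitations

* The ICAR spatial prior is intrinsic only; proper-CAR, Leroux and BYM2
  variants are out of scope, as are spatio-temporal extensions and
  geometry-derived adjacency.
* Single-model imputation only: no multiple-imputation pooling.
* With strongly spatially structured covariates, $\beta$ and $S$ are only
  weakly jointly identified (spatial confounding); the sampler handles the
  resulting ridge, but the data genuinely contain limited information, and
  credible intervals widen accordingly.
* The grid draws for non-conjugate standard deviations are exact only up
  to the 400-point grid; bounds (1e-3 to 20 on the log-spaced grid) cap
  the representable scales.
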