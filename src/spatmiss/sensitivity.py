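"""Prior sensitivity grid and the mediation screen.

The sensitivity analysis refits the spatial GLMM under five prior
configurations (vague Gamma precisions, bounded-uniform standard
deviations, half-normal and log-normal standard deviations — see
:func:`spatmiss.model.resolve_priors`) for both outcome families and
tabulates coefficient posteriors, residual variances and DIC side by side.
Robust conclusions should survive all ten fits.

The mediation screen asks whether a candidate covariate transmits part of
the exposure's effect: it compares the exposure coefficient from the
univariate model against the coefficient when one candidate at a time is
added, and flags a candidate when the coefficient moves by strictly more
than 10%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import RegionDataset
from .imputation import impute_mean
from .model import ModelConfig, PosteriorSummary, fit_spatial_glmm

MEDIATION_THRESHOLD_PCT = 10.0
COEF_FLOOR = 1e-6


@dataclass(frozen=True)
class PriorGridSpec:
    """Which (prior model, family) cells of the sensitivity grid to run."""

    models: tuple = (1, 2, 3, 4, 5)
    families: tuple = ("binomial", "poisson")
    iters: int = 4000
    burnin: int = 2000
    chains: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.models or not self.families:
            raise ValueError("models and families must be non-empty")
        bad = set(self.models) - {1, 2, 3, 4, 5}
        if bad:
            raise ValueError(f"unknown prior models {sorted(bad)}")


@dataclass(frozen=True)
class MediationRecord:
    """One candidate mediator's effect on the exposure coefficient."""

    covariate: str
    ses_coef_univariate: float
    ses_coef_bivariate: "float | None"
    pct_change: "float | None"
    flagged: "bool | None"


def subset_covariates(data: RegionDataset, names) -> RegionDataset:
    """Dataset restricted to a subset of covariate columns."""
    cols = [data.covariate_index(n) for n in names]
    return RegionDataset(
        region_ids=data.region_ids,
        Y=data.Y.copy(),
        n=data.n.copy(),
        X=data.X[:, cols].copy(),
        mask=data.mask[:, cols].copy(),
        covariate_names=tuple(names),
        lattice=data.lattice,
        E=None if data.E is None else data.E.copy(),
        centered=data.centered[cols].copy(),
        center_offsets=data.center_offsets[cols].copy(),
    )


@dataclass
class PriorGridResult:
    """Fits (or failures) for every (model, family) cell, plus a flat table."""

    fits: dict
    failures: dict
    table: pd.DataFrame

    def summary(self, model: int, family: str) -> PosteriorSummary:
        return self.fits[(model, family)]


def run_prior_grid(data: RegionDataset, spec: "PriorGridSpec | None" = None) -> PriorGridResult:
    """Fit the GLMM for each (prior model, family) pair from a shared seed.

    Individual fit failures are recorded and the grid continues. The table
    has one row per cell with the intercept, coefficient posteriors (mean
    and 95% CrI), residual variances and DIC.
    """
    spec = spec or PriorGridSpec()
    fits, failures, rows = {}, {}, []
    for family in spec.families:
        for model in spec.models:
            config = ModelConfig(
                family=family,
                imputation="mean",
                prior_model=model,
                iters=spec.iters,
                burnin=spec.burnin,
                chains=spec.chains,
                seed=spec.seed,
            )
            try:
                summ = fit_spatial_glmm(data, config)
            except Exception as exc:  # keep the grid alive on a single failure
                failures[(model, family)] = repr(exc)
                continue
            fits[(model, family)] = summ
            row = {
                "family": family,
                "model": model,
                "alpha": summ.alpha.mean,
                "alpha_lo": summ.alpha.lo,
                "alpha_hi": summ.alpha.hi,
            }
            for name, b, sig in zip(summ.covariate_names, summ.beta, summ.significant):
                row[f"beta_{name}"] = b.mean
                row[f"beta_{name}_lo"] = b.lo
                row[f"beta_{name}_hi"] = b.hi
                row[f"beta_{name}_sig"] = bool(sig)
            row["sigma_S2"] = summ.sigma_S2.mean
            row["sigma_U2"] = summ.sigma_U2.mean
            row["DIC"] = summ.dic.DIC
            row["pD"] = summ.dic.pD
            rows.append(row)
    return PriorGridResult(fits=fits, failures=failures, table=pd.DataFrame(rows))


def univariate_fits(data: RegionDataset, config: "ModelConfig | None" = None) -> pd.DataFrame:
    """One single-covariate fit per covariate, same random-effect structure.

    Returns a table with the coefficient posterior, CrI and significance
    flag per covariate; per-fit failures are isolated into an ``error``
    column.
    """
    config = config or ModelConfig()
    rows = []
    for name in data.covariate_names:
        sub = subset_covariates(data, [name])
        try:
            summ = fit_spatial_glmm(sub, config)
            b = summ.beta[0]
            rows.append(
                {
                    "covariate": name,
                    "coef": b.mean,
                    "lo": b.lo,
                    "hi": b.hi,
                    "significant": bool(summ.significant[0]),
                    "error": None,
                }
            )
        except Exception as exc:
            rows.append(
                {
                    "covariate": name,
                    "coef": np.nan,
                    "lo": np.nan,
                    "hi": np.nan,
                    "significant": None,
                    "error": repr(exc),
                }
            )
    return pd.DataFrame(rows)


def mediation_screen(
    data: RegionDataset,
    exposure: str = "ses",
    config: "ModelConfig | None" = None,
) -> list:
    """Coefficient-change screen for mediation of the exposure's effect.

    Fits the univariate exposure model as the baseline, then one bivariate
    model per other covariate, and reports the percentage change of the
    exposure coefficient. A change of strictly more than 10% flags the
    candidate as a potential mediator. Data are completed by mean
    imputation first (the selected method), matching the analysis
    sequencing of selection first, inference after.
    """
    config = config or ModelConfig()
    if exposure not in data.covariate_names:
        raise KeyError(f"unknown exposure {exposure!r}")
    j = data.covariate_index(exposure)
    if data.mask[:, j].any():
        raise ValueError(f"exposure {exposure!r} must be fully observed")
    work = impute_mean(data).completed if data.mask.any() else data
    base = fit_spatial_glmm(subset_covariates(work, [exposure]), config)
    coef_uni = base.beta[0].mean
    records = []
    for name in work.covariate_names:
        if name == exposure:
            continue
        summ = fit_spatial_glmm(subset_covariates(work, [exposure, name]), config)
        coef_biv = summ.beta[0].mean
        if abs(coef_uni) < COEF_FLOOR:
            records.append(
                MediationRecord(
                    covariate=name,
                    ses_coef_univariate=coef_uni,
                    ses_coef_bivariate=coef_biv,
                    pct_change=None,
                    flagged=None,
                )
            )
            continue
        pct = 100.0 * (coef_biv - coef_uni) / coef_uni
        records.append(
            MediationRecord(
                covariate=name,
                ses_coef_univariate=coef_uni,
                ses_coef_bivariate=coef_biv,
                pct_change=float(pct),
                flagged=bool(abs(pct) > MEDIATION_THRESHOLD_PCT),
            )
        )
    return records


def mediation_frame(records) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])
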