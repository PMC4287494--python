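"""Cross-validation comparison of imputation methods.

Regions with fully observed covariates are repeatedly split 90/10; the test
regions' survey covariates are masked, each imputation method fills them,
and the imputations are scored against the held-back truth with four
statistics per covariate and overall:

* RMSE of imputed vs observed values, computed per round and then averaged
  (mean and sd across rounds);
* relative bias ``(xhat_ij - xbar_j) / xbar_j`` where ``xbar_j`` is the
  mean of the training observations of covariate ``j`` — mean imputation
  has bias exactly zero by construction;
* mean width of the 95% credible interval per imputed cell;
* percentage of per-cell bias intervals containing zero bias.

The overall figures weight covariates equally (not by cell count). The
selection rule picks the method with the smallest overall RMSE, breaking
ties by smallest absolute overall bias, then lexicographically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import RegionDataset
from .imputation import MCMCSettings, impute
from .synthetic import SURVEY_COVARIATES

#: Cell-level score columns produced by :func:`score_round`.
RECORD_COLUMNS = (
    "method",
    "round",
    "region_id",
    "covariate",
    "truth",
    "imputed",
    "error",
    "bias",
    "ci_width",
    "covers_zero",
)


def complete_region_ids(data: RegionDataset) -> list:
    """Regions with no missing covariate cells (candidates for CV)."""
    full = ~data.mask.any(axis=1)
    return [rid for rid, ok in zip(data.region_ids, full) if ok]


def make_cv_splits(complete_ids, rounds: int, test_frac: float, seed: int = 0):
    """Seeded train/test splits over the fully observed regions.

    Each round draws ``ceil(test_frac * N)`` test regions uniformly without
    replacement; the rest train. Per-round seeds derive deterministically
    from ``(seed, round)`` so rounds are reproducible in isolation.
    """
    ids = list(complete_ids)
    N = len(ids)
    if rounds < 1:
        raise ValueError("need at least one round")
    if not 0.0 < test_frac < 1.0:
        raise ValueError("test_frac must be in (0, 1)")
    n_test = int(np.ceil(test_frac * N))
    if n_test == 0 or n_test >= N:
        raise ValueError(f"test split of size {n_test} out of {N} regions is degenerate")
    splits = []
    for r in range(rounds):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11_001, r]))
        test = sorted(rng.choice(N, size=n_test, replace=False).tolist())
        test_ids = [ids[i] for i in test]
        train_ids = [ids[i] for i in range(N) if i not in set(test)]
        splits.append({"round": r, "train": train_ids, "test": test_ids})
    return splits


def mask_test_regions(data: RegionDataset, test_ids, covariates=SURVEY_COVARIATES) -> RegionDataset:
    """Mask the survey covariates of the test regions jointly.

    Masking all scored covariates at once reproduces the block structure of
    real survey suppression; the ordinal SES column (fully observed in
    practice) stays available as a predictor for the multivariate method.
    """
    out = data.copy()
    idx = {rid: i for i, rid in enumerate(out.region_ids)}
    cols = [out.covariate_index(c) for c in covariates if c in out.covariate_names]
    for rid in test_ids:
        out.mask[idx[rid], cols] = True
    out.X[out.mask] = np.nan
    return out


def score_round(
    truth: RegionDataset,
    result,
    test_cells,
    train_means: dict,
    method: str,
    round_index: int,
) -> pd.DataFrame:
    """Score one round's imputations cell by cell.

    ``test_cells`` is a sequence of ``(region_id, covariate)`` keys;
    ``train_means[covariate]`` is the mean of the training observations.
    The bias interval for a cell is its credible interval mapped to the
    bias scale, so it covers zero bias exactly when the raw interval
    contains the training mean.
    """
    idx = {rid: i for i, rid in enumerate(truth.region_ids)}
    rows = []
    for rid, cov in test_cells:
        j = truth.covariate_index(cov)
        x_true = truth.X[idx[rid], j]
        if np.isnan(x_true):
            raise ValueError(f"test cell ({rid}, {cov}) has no observed truth")
        xbar = train_means[cov]
        if xbar == 0:
            raise ZeroDivisionError(f"training mean of {cov!r} is zero; bias undefined")
        xhat = result.point[(rid, cov)]
        lo, hi = result.interval[(rid, cov)]
        rows.append(
            {
                "method": method,
                "round": round_index,
                "region_id": rid,
                "covariate": cov,
                "truth": x_true,
                "imputed": xhat,
                "error": xhat - x_true,
                "bias": (xhat - xbar) / xbar,
                "ci_width": hi - lo,
                "covers_zero": bool(lo <= xbar <= hi),
            }
        )
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


@dataclass
class CVReport:
    """Aggregated cross-validation scores and the selected method."""

    per_method: dict
    rounds: int
    splits: list
    selected: str
    records: pd.DataFrame = field(default_factory=pd.DataFrame, repr=False)

    def to_frame(self) -> pd.DataFrame:
        """Comparison table: rows = covariates + Overall, columns per method."""
        rows = []
        covs = [c for c in next(iter(self.per_method.values()))["per_covariate"]]
        for cov in covs + ["Overall"]:
            row = {"covariate": cov}
            for method, stats in self.per_method.items():
                s = stats["overall"] if cov == "Overall" else stats["per_covariate"][cov]
                row[f"{method}_rmse_mean"] = s["rmse_mean"]
                row[f"{method}_rmse_sd"] = s["rmse_sd"]
                row[f"{method}_bias"] = s["bias_mean"]
                row[f"{method}_ci_width"] = s["ci_width_mean"]
                row[f"{method}_pct_covering_zero"] = s["pct_ci_covering_zero"]
            rows.append(row)
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "rounds": self.rounds,
            "selected": self.selected,
            "per_method": self.per_method,
        }


def aggregate_cv(
    records: pd.DataFrame,
    splits=None,
    pool_cells: bool = False,
    weight_by_cells: bool = False,
) -> CVReport:
    """Aggregate cell-level CV records into per-covariate and overall scores.

    ``pool_cells`` switches the per-covariate RMSE from
    mean-over-rounds-of-per-round-RMSE (default) to a single RMSE over all
    pooled cells. ``weight_by_cells`` switches the overall aggregation from
    equal covariate weighting (default) to equal cell weighting.
    Permutation-invariant to record order.
    """
    if records.empty:
        raise ValueError("no CV records to aggregate")
    per_method = {}
    for method, mrec in records.groupby("method", sort=True):
        per_cov = {}
        for cov, crec in mrec.groupby("covariate", sort=False):
            if pool_cells:
                rmse_mean = float(np.sqrt(np.mean(crec["error"] ** 2)))
                rmse_sd = float("nan")
            else:
                per_round = crec.groupby("round")["error"].apply(
                    lambda e: float(np.sqrt(np.mean(e**2)))
                )
                rmse_mean = float(per_round.mean())
                rmse_sd = float(per_round.std(ddof=1)) if len(per_round) > 1 else float("nan")
            per_cov[cov] = {
                "rmse_mean": rmse_mean,
                "rmse_sd": rmse_sd,
                "bias_mean": float(crec["bias"].mean()),
                "ci_width_mean": float(crec["ci_width"].mean()),
                "pct_ci_covering_zero": float(100.0 * crec["covers_zero"].mean()),
                "n_cells": int(len(crec)),
            }
        # keep the dataset's covariate ordering
        ordering = list(dict.fromkeys(records["covariate"]))
        per_cov = {c: per_cov[c] for c in ordering if c in per_cov}
        if weight_by_cells:
            w = np.array([s["n_cells"] for s in per_cov.values()], dtype=float)
        else:
            w = np.ones(len(per_cov))
        w = w / w.sum()

        def wavg(key):
            return float(np.sum(w * np.array([s[key] for s in per_cov.values()])))

        if pool_cells:
            overall_sd = float("nan")
        else:
            # overall per-round RMSE = equal-weight mean across covariates
            per_round_tbl = (
                mrec.assign(sq=mrec["error"] ** 2)
                .groupby(["covariate", "round"])["sq"]
                .mean()
                .pow(0.5)
                .groupby("round")
                .mean()
            )
            overall_sd = (
                float(per_round_tbl.std(ddof=1)) if len(per_round_tbl) > 1 else float("nan")
            )
        overall = {
            "rmse_mean": wavg("rmse_mean"),
            "rmse_sd": overall_sd,
            "bias_mean": wavg("bias_mean"),
            "ci_width_mean": wavg("ci_width_mean"),
            "pct_ci_covering_zero": wavg("pct_ci_covering_zero"),
            "n_cells": int(sum(s["n_cells"] for s in per_cov.values())),
        }
        per_method[method] = {"per_covariate": per_cov, "overall": overall}

    rounds = int(records["round"].nunique())
    report = CVReport(
        per_method=per_method,
        rounds=rounds,
        splits=splits or [],
        selected="",
        records=records,
    )
    report.selected = select_method(report)
    return report


def select_method(report: CVReport) -> str:
    """Smallest overall RMSE; ties by smallest |overall bias|, then name."""
    ranked = sorted(
        report.per_method.items(),
        key=lambda kv: (
            kv[1]["overall"]["rmse_mean"],
            abs(kv[1]["overall"]["bias_mean"]),
            kv[0],
        ),
    )
    return ranked[0][0]


def run_cross_validation(
    data: RegionDataset,
    methods=("mean", "mvn", "car"),
    rounds: int = 10,
    test_frac: float = 0.1,
    seed: int = 0,
    mcmc: "MCMCSettings | None" = None,
    covariates=SURVEY_COVARIATES,
) -> CVReport:
    """The full CV harness: split, mask, impute with each method, score.

    Imputation runs on the whole dataset (incomplete regions keep their
    real missingness and the full lattice is available for spatial
    borrowing); only the artificially masked test cells are scored.
    """
    mcmc = mcmc or MCMCSettings(iters=1500, burnin=500, chains=2)
    ids = complete_region_ids(data)
    splits = make_cv_splits(ids, rounds, test_frac, seed)
    idx = {rid: i for i, rid in enumerate(data.region_ids)}
    all_records = []
    for split in splits:
        masked = mask_test_regions(data, split["test"], covariates)
        test_cells = [
            (rid, cov)
            for rid in split["test"]
            for cov in covariates
            if cov in data.covariate_names
        ]
        train_means = {}
        for cov in covariates:
            if cov not in data.covariate_names:
                continue
            j = data.covariate_index(cov)
            obs = ~masked.mask[:, j]
            train_means[cov] = float(masked.X[obs, j].mean())
        for method in methods:
            if method == "mean":
                result = impute(masked, "mean")
            elif method == "mvn":
                result = impute(masked, "mvn", mcmc=mcmc, seed=seed + 13 * split["round"])
            elif method == "car":
                result = impute(
                    masked,
                    "car",
                    lattice=data.lattice,
                    mcmc=mcmc,
                    seed=seed + 13 * split["round"],
                )
            else:
                raise ValueError(f"unknown method {method!r}")
            all_records.append(
                score_round(data, result, test_cells, train_means, method, split["round"])
            )
    records = pd.concat(all_records, ignore_index=True)
    return aggregate_cv(records, splits=splits)
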