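import numpy as np
import pandas as pd
import pytest

import spatmiss as sm
from spatmiss.evaluation import (
    RECORD_COLUMNS,
    aggregate_cv,
    complete_region_ids,
    make_cv_splits,
    mask_test_regions,
    score_round,
    select_method,
)
from spatmiss.imputation import impute_mean

from conftest import make_dataset


class TestSplits:
    def test_39_regions_split_35_4(self):
        ids = [f"R{i}" for i in range(39)]
        splits = make_cv_splits(ids, rounds=10, test_frac=0.1, seed=0)
        assert len(splits) == 10
        for s in splits:
            assert len(s["train"]) == 35 and len(s["test"]) == 4
            assert sorted(s["train"] + s["test"]) == sorted(ids)

    def test_same_seed_identical_splits(self):
        ids = [f"R{i}" for i in range(20)]
        a = make_cv_splits(ids, 5, 0.1, seed=3)
        b = make_cv_splits(ids, 5, 0.1, seed=3)
        assert a == b

    def test_degenerate_split_rejected(self):
        with pytest.raises(ValueError):
            make_cv_splits(["A", "B"], 1, 0.9, seed=0)
        with pytest.raises(ValueError):
            make_cv_splits(["A", "B"], 1, 1.5, seed=0)

    def test_complete_ids_study_conditions(self, study_data):
        data, _ = study_data
        assert len(complete_region_ids(data)) == 39  # 71 - 32 incomplete


class TestScoreRound:
    def _tiny(self):
        X = np.array([[1.0, 5.0], [3.0, 7.0], [2.0, 6.0]])
        return make_dataset(X, names=("a", "b"))

    def test_perfect_imputation_zero_error(self):
        data = self._tiny()
        masked = data.copy()
        masked.mask[0, 0] = True
        masked.X[0, 0] = np.nan
        res = impute_mean(masked)
        res.point[("R0", "a")] = 1.0  # pretend a perfect imputer
        res.interval[("R0", "a")] = (1.0, 1.0)
        rec = score_round(data, res, [("R0", "a")], {"a": 2.5}, "mean", 0)
        assert rec["error"].iloc[0] == 0.0

    def test_hand_computed_fixture(self):
        # truth (1, 3), imputed (2, 2), training mean 2:
        # errors (1, -1) -> RMSE 1, biases (0, 0)
        data = self._tiny()
        masked = data.copy()
        masked.mask[:2, 0] = True
        masked.X[:2, 0] = np.nan
        res = impute_mean(masked)
        res.point[("R0", "a")] = 2.0
        res.point[("R1", "a")] = 2.0
        res.interval[("R0", "a")] = (2.0, 2.0)
        res.interval[("R1", "a")] = (2.0, 2.0)
        cells = [("R0", "a"), ("R1", "a")]
        rec = score_round(data, res, cells, {"a": 2.0}, "mean", 0)
        assert list(rec["error"]) == [1.0, -1.0]
        assert np.sqrt(np.mean(rec["error"] ** 2)) == 1.0
        assert list(rec["bias"]) == [0.0, 0.0]
        assert rec["covers_zero"].all()

    def test_mean_imputation_bias_identically_zero(self, study_data):
        data, _ = study_data
        complete = complete_region_ids(data)
        masked = mask_test_regions(data, complete[:4])
        res = impute_mean(masked)
        cells = [(rid, c) for rid, c in res.point if rid in complete[:4]]
        means = {}
        for c in set(c for _, c in cells):
            j = data.covariate_index(c)
            obs = ~masked.mask[:, j]
            means[c] = float(masked.X[obs, j].mean())
        rec = score_round(data, res, cells, means, "mean", 0)
        assert np.allclose(rec["bias"], 0.0)
        assert rec["covers_zero"].all()

    def test_zero_training_mean_rejected(self):
        data = self._tiny()
        masked = data.copy()
        masked.mask[0, 0] = True
        masked.X[0, 0] = np.nan
        res = impute_mean(masked)
        with pytest.raises(ZeroDivisionError):
            score_round(data, res, [("R0", "a")], {"a": 0.0}, "mean", 0)


def _records(rows):
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def _row(method, rnd, cov, error, bias=0.0, width=0.0, covers=True, rid="R0"):
    return {
        "method": method, "round": rnd, "region_id": rid, "covariate": cov,
        "truth": 0.0, "imputed": error, "error": error, "bias": bias,
        "ci_width": width, "covers_zero": covers,
    }


class TestAggregation:
    def test_equal_covariate_weighting(self):
        recs = _records([
            _row("m", 0, "a", 10.0),
            _row("m", 0, "b", 20.0),
        ])
        rep = aggregate_cv(recs)
        assert rep.per_method["m"]["overall"]["rmse_mean"] == 15.0

    def test_singleton_round_has_nan_sd(self):
        recs = _records([_row("m", 0, "a", 3.0)])
        rep = aggregate_cv(recs)
        s = rep.per_method["m"]["per_covariate"]["a"]
        assert s["rmse_mean"] == 3.0 and np.isnan(s["rmse_sd"])

    def test_two_cov_two_rounds_against_brute_force(self):
        rng = np.random.default_rng(9)
        rows = []
        for rnd in range(2):
            for cov in ("a", "b"):
                for i in range(3):
                    rows.append(_row("m", rnd, cov, float(rng.normal()),
                                     bias=float(rng.normal()),
                                     width=float(rng.random()),
                                     covers=bool(rng.random() < 0.5),
                                     rid=f"R{i}"))
        recs = _records(rows)
        rep = aggregate_cv(recs)
        # brute-force recomputation, independent of the implementation
        for cov in ("a", "b"):
            sub = recs[recs["covariate"] == cov]
            per_round = []
            for rnd in (0, 1):
                e = sub[sub["round"] == rnd]["error"].to_numpy()
                per_round.append(np.sqrt(np.mean(e**2)))
            s = rep.per_method["m"]["per_covariate"][cov]
            assert s["rmse_mean"] == pytest.approx(np.mean(per_round))
            assert s["rmse_sd"] == pytest.approx(np.std(per_round, ddof=1))
            assert s["bias_mean"] == pytest.approx(sub["bias"].mean())
            assert s["ci_width_mean"] == pytest.approx(sub["ci_width"].mean())
            assert s["pct_ci_covering_zero"] == pytest.approx(100 * sub["covers_zero"].mean())
        overall = rep.per_method["m"]["overall"]
        expect = np.mean([rep.per_method["m"]["per_covariate"][c]["rmse_mean"] for c in "ab"])
        assert overall["rmse_mean"] == pytest.approx(expect)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        rows = [
            _row("m", rnd, cov, float(rng.normal()), rid=f"R{i}")
            for rnd in range(3) for cov in ("a", "b") for i in range(2)
        ]
        recs = _records(rows)
        shuffled = recs.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = aggregate_cv(recs).per_method["m"]["overall"]
        b = aggregate_cv(shuffled).per_method["m"]["overall"]
        assert a == b

    def test_cell_weighting_flag_changes_overall(self):
        recs = _records(
            [_row("m", 0, "a", 10.0, rid=f"R{i}") for i in range(9)]
            + [_row("m", 0, "b", 20.0)]
        )
        equal = aggregate_cv(recs).per_method["m"]["overall"]["rmse_mean"]
        cellw = aggregate_cv(recs, weight_by_cells=True).per_method["m"]["overall"]["rmse_mean"]
        assert equal == 15.0
        assert cellw == pytest.approx((9 * 10 + 20) / 10)


class TestSelection:
    def _report(self, overalls):
        per_method = {
            m: {"per_covariate": {}, "overall": {"rmse_mean": r, "bias_mean": b}}
            for m, (r, b) in overalls.items()
        }
        return sm.CVReport(per_method=per_method, rounds=1, splits=[], selected="")

    def test_smallest_rmse_wins(self):
        rep = self._report({"mean": (32.5, 0.0), "mvn": (71.1, 0.076), "car": (46.1, 0.113)})
        assert select_method(rep) == "mean"

    def test_singleton(self):
        rep = self._report({"car": (5.0, 0.1)})
        assert select_method(rep) == "car"

    def test_tie_broken_by_bias(self):
        rep = self._report({"x": (5.0, 0.08), "y": (5.0, 0.0)})
        assert select_method(rep) == "y"

    def test_full_tie_lexicographic(self):
        rep = self._report({"b": (5.0, 0.1), "a": (5.0, 0.1)})
        assert select_method(rep) == "a"


class TestMaskTestRegions:
    def test_block_masking_and_ses_kept(self, study_data):
        data, _ = study_data
        ids = complete_region_ids(data)[:4]
        masked = mask_test_regions(data, ids)
        idx = {r: i for i, r in enumerate(data.region_ids)}
        for rid in ids:
            i = idx[rid]
            assert not masked.mask[i, masked.covariate_index("ses")]
            for cov in ("over45", "overweight", "smokers", "inactive", "fruit", "veg"):
                assert masked.mask[i, masked.covariate_index(cov)]
        # original missingness is retained
        assert masked.mask.sum() == data.mask.sum() + 4 * 6
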