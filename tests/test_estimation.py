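"""Indicator screening, MLR/RF estimation with LOOCV, group comparison."""

import numpy as np
import pandas as pd
import pytest

from ricenc.estimation import (
    compare_groups,
    fit_and_validate,
    indicator_r2,
    select_predictors,
    universal_from_estimates,
)
from ricenc.exceptions import InsufficientDataError
from ricenc.synthetic import FEATURE_COLUMNS, SyntheticConfig, generate_trial, generate_features


@pytest.fixture(scope="module")
def linked_features():
    cfg = SyntheticConfig(n_groups=60, seed=5)
    _, truth = generate_trial(cfg)
    feats = generate_features(truth, cfg)
    a = np.array([t.true_a for t in truth])
    b = np.array([t.true_b for t in truth])
    return feats, a, b


class TestScreening:
    def test_identity_indicator_scores_one(self):
        feats = pd.DataFrame({c: np.random.default_rng(1).normal(size=20)
                              for c in FEATURE_COLUMNS})
        y = feats["PH"].to_numpy()
        table = indicator_r2(feats, y)
        assert table.loc[table.indicator == "PH", "r2"].iloc[0] == pytest.approx(1.0)

    def test_constant_indicator_flagged_not_erroring(self):
        rng = np.random.default_rng(2)
        feats = pd.DataFrame({c: rng.normal(size=20) for c in FEATURE_COLUMNS})
        feats["TGW"] = 26.0
        table = indicator_r2(feats, rng.normal(size=20))
        row = table[table.indicator == "TGW"].iloc[0]
        assert row["r2"] == 0.0 and bool(row["degenerate"])

    def test_affine_transform_invariance(self, linked_features):
        feats, a, _ = linked_features
        t1 = indicator_r2(feats, a)
        shifted = feats.copy()
        shifted["PH"] = 3.0 * shifted["PH"] - 40.0
        t2 = indicator_r2(shifted, a)
        assert t2.loc[t2.indicator == "PH", "r2"].iloc[0] == pytest.approx(
            t1.loc[t1.indicator == "PH", "r2"].iloc[0], rel=1e-9
        )

    def test_generator_links_drive_selection(self, linked_features):
        feats, a, b = linked_features
        assert set(select_predictors(indicator_r2(feats, a))) == {
            "PH", "SLA-T", "DW-V"
        }
        assert set(select_predictors(indicator_r2(feats, b))) == {
            "AGDD-T", "SLR-T", "LAI-V"
        }

    def test_tie_break_uses_column_order(self):
        table = pd.DataFrame(
            {"indicator": FEATURE_COLUMNS, "r2": 0.5, "degenerate": False}
        )
        assert select_predictors(table, k=3) == FEATURE_COLUMNS[:3]
        assert select_predictors(table, k=14) == FEATURE_COLUMNS


class TestFitAndValidate:
    def test_exact_linear_relation_mlr(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(15, 3)), columns=list("xyz"))
        y = 2.0 * X["x"] - 1.5 * X["y"] + 0.3
        rep = fit_and_validate("MLR", X, y)
        assert rep.modeling_r2 == pytest.approx(1.0)
        assert rep.loocv_r2 == pytest.approx(1.0)
        assert rep.loocv_rrmse == pytest.approx(0.0, abs=1e-9)

    def test_constant_target_short_circuits(self):
        X = pd.DataFrame(np.random.default_rng(4).normal(size=(10, 2)),
                         columns=["u", "v"])
        for method in ("MLR", "RF"):
            rep = fit_and_validate(method, X, np.full(10, 3.3))
            assert rep.loocv_rrmse == 0.0
            assert np.allclose(rep.loocv_predictions, 3.3)

    def test_loocv_covers_each_record_once(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(size=(12, 2)), columns=["u", "v"])
        y = rng.normal(size=12)
        rep = fit_and_validate("RF", X, y, rf_ntree=30, rf_mtry=1, seed=0)
        assert rep.loocv_predictions.shape == (12,)

    def test_rf_mtry_auto_scans_feasible_range(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame(rng.normal(size=(12, 3)), columns=list("pqr"))
        y = X["p"] + 0.1 * rng.normal(size=12)
        rep = fit_and_validate("RF", X, y, rf_ntree=30, rf_mtry="auto", seed=0)
        assert rep.mtry in (1, 2, 3)

    def test_loocv_order_invariance(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(rng.normal(size=(10, 2)), columns=["u", "v"])
        y = pd.Series(X["u"] ** 2 + 0.05 * rng.normal(size=10))
        rep1 = fit_and_validate("MLR", X, y)
        perm = rng.permutation(10)
        rep2 = fit_and_validate("MLR", X.iloc[perm], y.iloc[perm])
        assert rep1.loocv_rrmse == pytest.approx(rep2.loocv_rrmse, rel=1e-9)

    def test_underdetermined_mlr_rejected(self):
        X = pd.DataFrame(np.eye(4), columns=list("abcd"))
        with pytest.raises(InsufficientDataError):
            fit_and_validate("MLR", X, np.arange(4.0))

    def test_rf_beats_mlr_on_nonlinear_links(self, linked_features):
        feats, _, b = linked_features
        preds = select_predictors(indicator_r2(feats, b))
        mlr = fit_and_validate("MLR", feats[preds], b, target="b")
        rf = fit_and_validate(
            "RF", feats[preds], b, target="b", rf_ntree=150, rf_mtry=2, seed=0
        )
        assert rf.loocv_rrmse < mlr.loocv_rrmse


class TestUniversalAveraging:
    def test_hand_mean(self):
        c = universal_from_estimates([3.4, 3.8], [0.3, 0.4])
        assert (c.a, c.b) == (pytest.approx(3.6), pytest.approx(0.35))

    def test_identical_groups(self):
        c = universal_from_estimates([3.5, 3.5, 3.5], [0.3, 0.3, 0.3],
                                     provenance="Average")
        assert c.a == 3.5 and c.b == pytest.approx(0.3)
        assert c.provenance == "Average"

    def test_population_mean_recovered(self, linked_features):
        _, a, b = linked_features
        c = universal_from_estimates(a, b)
        assert c.a == pytest.approx(3.56, abs=3 * 0.21 / np.sqrt(len(a)))
        assert c.b == pytest.approx(0.34, abs=3 * 0.08 / np.sqrt(len(b)))


class TestCompareGroups:
    def test_disjoint_distributions_get_distinct_letters(self, rng):
        letters = compare_groups(
            {"L1": rng.normal(3.0, 0.01, 2000),
             "L2": rng.normal(4.0, 0.01, 2000)}
        )
        assert set(letters["L1"]) & set(letters["L2"]) == set()

    def test_identical_distributions_share_a_letter(self, rng):
        x = rng.normal(3.5, 0.2, 2000)
        letters = compare_groups({"L1": x, "L2": x + 0.0})
        assert letters["L1"] == letters["L2"] == "a"

    def test_three_levels_partial_overlap(self, rng):
        letters = compare_groups(
            {
                "L1": rng.normal(3.0, 0.01, 2000),
                "L2": rng.normal(3.0, 0.01, 2000),
                "L3": rng.normal(4.0, 0.01, 2000),
            }
        )
        assert letters["L1"] == letters["L2"]
        assert set(letters["L3"]) & set(letters["L1"]) == set()
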