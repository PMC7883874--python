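"""Accuracy metrics, splitting, the OOB forest and the year-effect tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fusionfield.modeling import (RandomForestOOB, compact_letters, dunn_test,
                                  fit_rf, norm_dev, r2_val, repeated_modeling,
                                  rrmsep, stratified_split, year_effect_test)


class TestR2Val:
    def test_perfect_prediction(self):
        assert r2_val([1, 2, 3], [1, 2, 3]) == 1.0

    def test_hand_example(self):
        # SSres = 2, SStot = 2
        assert r2_val([1, 2, 3], [2, 2, 2]) == pytest.approx(0.0)

    def test_mean_prediction_is_zero(self):
        y = np.array([4.0, 6.0, 8.0])
        assert r2_val(y, np.full(3, y.mean())) == pytest.approx(0.0)

    def test_predicted_mean_convention_differs(self):
        y, yhat = np.array([1.0, 2.0, 3.0]), np.array([2.5, 2.5, 2.5])
        assert r2_val(y, yhat, ybar="observed") != \
            r2_val(y, yhat, ybar="predicted")

    def test_constant_observed_errors(self):
        with pytest.raises(ValueError):
            r2_val([2.0, 2.0], [1.0, 3.0])


class TestRRMSEP:
    def test_hand_example(self):
        assert rrmsep([0.0, 10.0], [1.0, 9.0]) == pytest.approx(10.0)

    def test_perfect_prediction(self):
        assert rrmsep([0.0, 5.0, 10.0], [0.0, 5.0, 10.0]) == 0.0

    @pytest.mark.parametrize("c", [0.1, 3.0])
    def test_scale_invariance(self, c, rng):
        y = rng.random(20) * 10
        yhat = y + rng.normal(0, 1, 20)
        assert rrmsep(c * y, c * yhat) == pytest.approx(rrmsep(y, yhat))

    def test_zero_range_errors(self):
        with pytest.raises(ValueError):
            rrmsep([1.0, 1.0], [1.0, 2.0])


class TestNormDev:
    def test_values_and_antisymmetry(self):
        assert norm_dev([1.0], [3.0])[0] == pytest.approx(0.5)
        assert norm_dev([3.0], [1.0])[0] == pytest.approx(-0.5)
        assert norm_dev([2.0], [2.0])[0] == 0.0

    def test_bounded_for_positive_values(self, rng):
        y = rng.random(100) + 0.01
        yhat = rng.random(100) + 0.01
        nd = norm_dev(y, yhat)
        assert (np.abs(nd) <= 1.0).all()

    def test_zero_sum_warns_nan(self):
        with pytest.warns(UserWarning):
            out = norm_dev([0.0], [0.0])
        assert np.isnan(out[0])


def design_table(n_per=4):
    rows = []
    for year in (1, 2):
        for harvest in (1, 2, 3):
            for treat in ("CG", "LG", "G_CG"):
                for k in range(n_per):
                    rows.append({"plot_id": f"{treat}_{k}", "year": year,
                                 "harvest": harvest, "treatment": treat})
    return pd.DataFrame(rows)


class TestStratifiedSplit:
    def test_coverage_disjoint_exhaustive(self, default_bundle):
        table = default_bundle.truth
        cal, val = stratified_split(table, seed=11)
        assert len(val) == 35 and len(cal) == 105
        assert set(cal) | set(val) == set(range(140))
        assert not set(cal) & set(val)
        for key in ("year", "harvest", "treatment"):
            for part in (cal, val):
                assert set(table[key].iloc[part]) == set(table[key])

    def test_same_seed_identical(self):
        t = design_table()
        a = stratified_split(t, seed=5)
        b = stratified_split(t, seed=5)
        np.testing.assert_array_equal(a[1], b[1])

    def test_singleton_stratum_errors(self):
        t = design_table()
        t = pd.concat([t, pd.DataFrame([{"plot_id": "x", "year": 3,
                                         "harvest": 1, "treatment": "CG"}])])
        with pytest.raises(ValueError, match="year"):
            stratified_split(t.reset_index(drop=True), seed=0)


class TestRandomForestOOB:
    def test_constant_response(self):
        X = np.random.default_rng(0).random((30, 3))
        rf = fit_rf(X, np.full(30, 5.0), n_trees=30, seed=0)
        assert rf.predict(X) == pytest.approx(5.0)
        assert rf.oob_mse() == pytest.approx(0.0)

    def test_recovers_linear_signal(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(200, 5))
        y = 3.0 * X[:, 0] + rng.normal(0, 0.3, 200)
        r2s = []
        for seed in range(3):
            rf = fit_rf(X[:150], y[:150], n_trees=150, seed=seed)
            r2s.append(r2_val(y[150:], rf.predict(X[150:])))
        assert np.median(r2s) > 0.8

    def test_importance_ranks_informative_first(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(150, 6))
        y = 2.0 * X[:, 3] + rng.normal(0, 0.2, 150)
        rf = fit_rf(X, y, n_trees=150, seed=0)
        imp = rf.permutation_importance(rng)
        assert np.argmax(imp) == 3

    def test_mtry_clamped_with_warning(self):
        X = np.random.default_rng(0).random((30, 3))
        y = X[:, 0]
        with pytest.warns(UserWarning, match="clamp"):
            fit_rf(X, y, mtry=10, n_trees=10, seed=0)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(50, 4))
        y = X[:, 0] + rng.normal(0, 0.1, 50)
        a = fit_rf(X, y, n_trees=25, seed=7).predict(X)
        b = fit_rf(X, y, n_trees=25, seed=7).predict(X)
        np.testing.assert_array_equal(a, b)


class TestRepeatedModeling:
    def test_single_split_and_metric_recomputation(self, default_bundle):
        table = default_bundle.truth.rename(columns={"FM_t_ha": "FM"})
        preds = ["mean_height_m", "cover", "legume_prop"]
        s = repeated_modeling(table, preds, "FM", n_splits=1, master_seed=4,
                              n_trees=60, tune=False)
        assert len(s.splits) == 1
        sp = s.splits[0]
        # metrics agree with independent recomputation from stored values
        assert sp.r2_val == pytest.approx(
            1 - ((sp.observed - sp.predicted) ** 2).sum()
            / ((sp.observed - sp.observed.mean()) ** 2).sum(), abs=1e-10)
        assert sp.rrmsep == pytest.approx(
            100 * np.sqrt(((sp.observed - sp.predicted) ** 2).mean())
            / (sp.observed.max() - sp.observed.min()), abs=1e-10)

    def test_validation_rows_disjoint_exhaustive_per_split(self, default_bundle):
        table = default_bundle.truth.rename(columns={"FM_t_ha": "FM"})
        s = repeated_modeling(table, ["mean_height_m", "cover"], "FM",
                              n_splits=3, master_seed=1, n_trees=40,
                              tune=False)
        n = len(table)
        for sp in s.splits:
            assert len(np.unique(sp.val_index)) == len(sp.val_index)
            assert len(sp.val_index) == 35


class TestDunnAndKruskal:
    def test_two_group_dunn_consistent_with_kruskal(self, rng):
        a = rng.normal(0, 1, 20)
        b = rng.normal(0.8, 1, 25)
        H, p_kw = stats.kruskal(a, b)
        dunn = dunn_test({"a": a, "b": b})
        # for two groups z^2 = H, so the p-values coincide
        assert dunn["z"].iloc[0] ** 2 == pytest.approx(H, rel=1e-9)
        assert dunn["p"].iloc[0] == pytest.approx(p_kw, rel=1e-6)

    def test_holm_adjustment_monotone(self, rng):
        groups = {k: rng.normal(m, 1, 15)
                  for k, m in {"a": 0, "b": 0.5, "c": 2.0}.items()}
        dunn = dunn_test(groups)
        assert (dunn["p_adjusted"] >= dunn["p"] - 1e-12).all()
        assert (dunn["p_adjusted"] <= 1.0).all()

    def test_compact_letters_share_letter_iff_not_significant(self):
        sig = {frozenset(("x", "z")): True, frozenset(("x", "y")): False,
               frozenset(("y", "z")): False}
        letters = compact_letters(["x", "y", "z"], sig)
        assert set(letters["x"]) & set(letters["z"]) == set()
        assert set(letters["x"]) & set(letters["y"])

    def test_year_effect_report_structure(self, rng):
        records = pd.DataFrame({
            "mixture": ["CG"] * 40 + ["LG"] * 40,
            "year": ([1] * 20 + [2] * 20) * 2,
            "norm_dev": np.r_[rng.normal(0, 0.1, 20),
                              rng.normal(0.3, 0.1, 20),
                              rng.normal(0, 0.1, 40)],
        })
        report = year_effect_test(records)
        assert report["CG"]["p"] < 0.01
        assert report["LG"]["p"] > 0.01
        assert report["CG"]["letters"][1] != report["CG"]["letters"][2]
        assert report["LG"]["letters"][1] == report["LG"]["letters"][2]

    def test_degenerate_groups_error(self):
        records = pd.DataFrame({"mixture": ["CG"] * 6, "year": [1, 1, 1, 2, 2, 2],
                                "norm_dev": [0.5] * 6})
        with pytest.raises(ValueError, match="tied"):
            year_effect_test(records)
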