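"""Feature selection, RF/SVM training, prediction and persistence.

Model tests run on small planted-signal fixtures (100+100 molecules,
5 informative + 10 noise descriptors, class separation 3) with reduced
grids so the whole suite stays fast while still exercising the scan,
tie-breaking, importance and determinism contracts.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cypscreen import (
    DescriptorMatrix,
    FixtureSpec,
    HyperGrid,
    ImportanceProfile,
    gen_descriptor_table,
    load_bundle,
    mean_gini_importance,
    mtry_upper_bound,
    predict,
    save_bundle,
    scan_rf_hyperparams,
    select_descriptors,
    standardize,
    train_rf,
    train_svm_rbf,
)
from cypscreen.errors import CypscreenError

SMALL_GRID = HyperGrid(ntree=(25, 50), mtry=(2, 3))


class TestMtryUpperBound:
    @pytest.mark.parametrize("p,expected", [(177, 13), (1, 1), (100, 10), (2, 1), (50, 7)])
    def test_floor_sqrt(self, p, expected):
        assert mtry_upper_bound(p) == expected

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            mtry_upper_bound(0)

    def test_default_mtry_grid_spans_5_to_ceiling(self):
        assert HyperGrid().mtry_for(177) == tuple(range(5, 14))
        assert HyperGrid().mtry_for(9) == (3,)


class TestHyperGrid:
    def test_cost_grid_is_ten_powers_of_two(self):
        costs = HyperGrid().costs
        assert len(costs) == 10
        assert costs[0] == 0.25 and costs[-1] == 128.0
        assert all(b / a == 2.0 for a, b in zip(costs, costs[1:]))


class TestScanRF:
    def test_separable_data_high_accuracy(self, small_data):
        matrix, labels = small_data
        result = scan_rf_hyperparams(matrix, labels, SMALL_GRID, cv=(10, 2), seed=1)
        assert result.winner["mean_accuracy"] >= 0.95

    def test_permuted_labels_chance_level(self, small_data):
        matrix, labels = small_data
        rng = np.random.default_rng(7)
        permuted = list(rng.permutation(labels))
        result = scan_rf_hyperparams(matrix, permuted, SMALL_GRID, cv=(10, 2), seed=1)
        # 99% binomial band around 0.5 for n held-out predictions
        n = len(labels)
        lo, hi = stats.binom.ppf([0.005, 0.995], n, 0.5) / n
        assert lo <= result.winner["mean_accuracy"] <= hi

    def test_deterministic(self, small_data):
        matrix, labels = small_data
        a = scan_rf_hyperparams(matrix, labels, SMALL_GRID, cv=(5, 1), seed=3)
        b = scan_rf_hyperparams(matrix, labels, SMALL_GRID, cv=(5, 1), seed=3)
        assert a == b

    def test_tie_breaks_prefer_smaller_ntree(self, small_data):
        # effect size 3 saturates accuracy, so ties are likely: the winner
        # must never be dominated by an equal-accuracy cheaper point
        matrix, labels = small_data
        result = scan_rf_hyperparams(matrix, labels, SMALL_GRID, cv=(5, 1), seed=2)
        best = result.winner["mean_accuracy"]
        cheaper = [
            e for e in result.entries
            if e["mean_accuracy"] == best
            and (e["ntree"], e["mtry"]) < (result.winner["ntree"], result.winner["mtry"])
        ]
        assert cheaper == []

    def test_single_class_errors(self, small_data):
        matrix, labels = small_data
        with pytest.raises(CypscreenError):
            scan_rf_hyperparams(matrix, ["inhibitor"] * len(labels), SMALL_GRID, seed=0)


class TestMeanGiniImportance:
    def test_single_run_equals_one_forest(self, small_data):
        from sklearn.ensemble import RandomForestClassifier

        matrix, labels = small_data
        profile = mean_gini_importance(
            matrix, labels, params={"ntree": 50, "mtry": 3}, n_runs=1, seed=10
        )
        forest = RandomForestClassifier(n_estimators=50, max_features=3, random_state=10, n_jobs=1)
        y = np.array([1 if l == "inhibitor" else 0 for l in labels])
        forest.fit(matrix.data.to_numpy(), y)
        assert np.allclose(profile.importances.to_numpy(), forest.feature_importances_)

    def test_planted_features_rank_top(self, small_data):
        matrix, labels = small_data
        profile = mean_gini_importance(
            matrix, labels, params={"ntree": 50, "mtry": 3}, n_runs=20, seed=0
        )
        top5 = set(select_descriptors(profile, top_k=5))
        assert top5 == {f"inf.{i}" for i in range(1, 6)}

    def test_pure_noise_importances_flat(self):
        spec = FixtureSpec(
            n_active=80, n_inactive=80, n_informative=0, n_noise=30, effect_size=0.0, seed=5
        )
        matrix, labels = gen_descriptor_table(spec)
        profile = mean_gini_importance(
            matrix, labels, params={"ntree": 50, "mtry": 5}, n_runs=100, seed=5
        )
        imp = profile.importances
        assert imp.max() / imp.median() < 3

    def test_mean_stabilizes_across_disjoint_batches(self, small_data):
        """Two disjoint run batches with different seeds agree on the
        top-5 descriptor set (importance-mean convergence)."""
        matrix, labels = small_data
        hits = 0
        for trial in range(5):
            a = mean_gini_importance(
                matrix, labels, params={"ntree": 50, "mtry": 3}, n_runs=30, seed=1000 * trial
            )
            b = mean_gini_importance(
                matrix, labels, params={"ntree": 50, "mtry": 3}, n_runs=30, seed=1000 * trial + 500
            )
            if set(select_descriptors(a, top_k=5)) == set(select_descriptors(b, top_k=5)):
                hits += 1
        assert hits >= 4

    def test_invalid_runs(self, small_data):
        matrix, labels = small_data
        with pytest.raises(ValueError):
            mean_gini_importance(matrix, labels, n_runs=0)


class TestSelectDescriptors:
    def _profile(self, mapping):
        return ImportanceProfile(
            importances=pd.Series(mapping), n_runs=1, params={}, seed=0
        )

    def test_top_k_ordering(self):
        assert select_descriptors(self._profile({"a": 5.0, "b": 3.0, "c": 1.0}), top_k=2) == ["a", "b"]

    def test_above_threshold(self):
        profile = self._profile({f"d{i:02d}": float(i) for i in range(50)})
        got = select_descriptors(profile, above_threshold=20.0)
        assert len(got) == 29  # strictly greater than 20
        assert got[0] == "d49"

    def test_tie_broken_alphabetically(self):
        got = select_descriptors(self._profile({"z": 2.0, "a": 2.0, "m": 9.0}), top_k=2)
        assert got == ["m", "a"]

    def test_k_too_large_errors(self):
        with pytest.raises(ValueError):
            select_descriptors(self._profile({"a": 1.0}), top_k=2)

    def test_exactly_one_mode(self):
        with pytest.raises(ValueError):
            select_descriptors(self._profile({"a": 1.0}))


class TestTrainRF:
    def test_separable_accuracy_and_resubstitution(self, small_data):
        matrix, labels = small_data
        bundle, cv = train_rf(matrix, labels, SMALL_GRID, cv=(10, 2), seed=4)
        assert cv.winner["mean_accuracy"] >= 0.95
        preds, scores = predict(bundle, matrix)
        resub = np.mean([p == t for p, t in zip(preds, labels)])
        assert resub >= cv.winner["mean_accuracy"]
        assert ((scores >= 0) & (scores <= 1)).all()

    def test_deterministic_predictions(self, small_data):
        matrix, labels = small_data
        b1, _ = train_rf(matrix, labels, SMALL_GRID, cv=(5, 1), seed=8)
        b2, _ = train_rf(matrix, labels, SMALL_GRID, cv=(5, 1), seed=8)
        assert predict(b1, matrix)[0] == predict(b2, matrix)[0]

    def test_more_informative_features_never_hurt(self):
        """Expected CV accuracy is monotone in the number of planted
        informative descriptors (paired across seeds, sign test)."""
        wins = ties = 0
        for seed in range(6):
            accs = {}
            for k in (1, 5):
                spec = FixtureSpec(
                    n_active=60, n_inactive=60, n_informative=k, n_noise=10,
                    effect_size=1.5, seed=seed,
                )
                matrix, labels = gen_descriptor_table(spec)
                r = scan_rf_hyperparams(matrix, labels, HyperGrid(ntree=(50,), mtry=(3,)),
                                        cv=(5, 1), seed=seed)
                accs[k] = r.winner["mean_accuracy"]
            if accs[5] > accs[1]:
                wins += 1
            elif accs[5] == accs[1]:
                ties += 1
        assert wins + ties >= 5  # one-sided sign check at 6 paired seeds


@pytest.fixture(scope="module")
def scaled(small_data):
    matrix, labels = small_data
    scaled, params = standardize(matrix)
    return scaled, params, labels


@pytest.fixture(scope="module")
def rf_bundle(small_data):
    matrix, labels = small_data
    b, _ = train_rf(matrix, labels, HyperGrid(ntree=(50,), mtry=(3,)), cv=(5, 1), seed=9)
    return b


class TestTrainSVM:
    def test_separable_accuracy(self, scaled):
        m, params, labels = scaled
        grid = HyperGrid(costs=(1.0, 8.0), sigma_multipliers=(1.0,))
        bundle, cv = train_svm_rbf(m, labels, params, grid, cv=(10, 2), seed=5)
        assert cv.winner["mean_accuracy"] >= 0.95

    def test_unscaled_input_rejected(self, small_data):
        matrix, labels = small_data
        _, params = standardize(matrix)
        with pytest.raises(CypscreenError, match="standardized"):
            train_svm_rbf(matrix, labels, params, cv=(5, 1), seed=0)

    def test_deterministic(self, scaled):
        m, params, labels = scaled
        grid = HyperGrid(costs=(1.0, 4.0), sigma_multipliers=(1.0,))
        b1, r1 = train_svm_rbf(m, labels, params, grid, cv=(5, 1), seed=6)
        b2, r2 = train_svm_rbf(m, labels, params, grid, cv=(5, 1), seed=6)
        assert r1.winner == r2.winner

    def test_predict_applies_scaling_internally(self, small_data, scaled):
        raw, labels = small_data
        m, params, _ = scaled
        grid = HyperGrid(costs=(1.0,), sigma_multipliers=(1.0,))
        bundle, _ = train_svm_rbf(m, labels, params, grid, cv=(5, 1), seed=7)
        preds, _ = predict(bundle, raw)  # raw input: bundle scales it
        acc = np.mean([p == t for p, t in zip(preds, labels)])
        assert acc >= 0.95


class TestPredictContract:
    def test_extra_columns_ignored(self, small_data, rf_bundle):
        matrix, labels = small_data
        extra = DescriptorMatrix(data=matrix.data.assign(**{"junk": 1.0 + np.arange(len(matrix.data))}))
        assert predict(rf_bundle, extra)[0] == predict(rf_bundle, matrix)[0]

    def test_missing_column_errors_naming_it(self, small_data, rf_bundle):
        matrix, _ = small_data
        broken = DescriptorMatrix(data=matrix.data.drop(columns=["inf.2"]))
        with pytest.raises(CypscreenError, match="inf.2"):
            predict(rf_bundle, broken)

    def test_row_order_preserved(self, small_data, rf_bundle):
        matrix, _ = small_data
        rev = DescriptorMatrix(data=matrix.data.iloc[::-1])
        assert predict(rf_bundle, rev)[0] == predict(rf_bundle, matrix)[0][::-1]


class TestBundleRoundtrip:
    @pytest.mark.parametrize("algo", ["rf", "svm"])
    def test_save_load_predict_identical(self, small_data, tmp_path, algo):
        matrix, labels = small_data
        if algo == "rf":
            bundle, _ = train_rf(matrix, labels, HyperGrid(ntree=(25,), mtry=(3,)), cv=(5, 1), seed=11)
        else:
            scaled, params = standardize(matrix)
            bundle, _ = train_svm_rbf(
                matrix=scaled, labels=labels, scaling=params,
                grid=HyperGrid(costs=(1.0,), sigma_multipliers=(1.0,)), cv=(5, 1), seed=11,
            )
        before = predict(bundle, matrix)
        path = tmp_path / "model.bundle"
        save_bundle(bundle, path)
        loaded = load_bundle(path)
        after = predict(loaded, matrix)
        assert before[0] == after[0]
        assert np.array_equal(before[1], after[1])

    def test_version_mismatch_refused(self, small_data, tmp_path):
        import joblib

        matrix, labels = small_data
        bundle, _ = train_rf(matrix, labels, HyperGrid(ntree=(25,), mtry=(3,)), cv=(5, 1), seed=12)
        path = tmp_path / "model.bundle"
        save_bundle(bundle, path)
        payload = joblib.load(path)
        payload["schema_version"] = 99
        joblib.dump(payload, path)
        from cypscreen.errors import BundleError

        with pytest.raises(BundleError):
            load_bundle(path)
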