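import numpy as np
import pytest

from conftest import toy_feature_table
from sparecg import ml_harness as mh


class TestConfusionMetrics:
    def test_male_70s_worked_example(self):
        acc, sens, spec = mh.confusion_metrics(16, 7, 0, 23)
        assert acc == pytest.approx(39 / 46)
        assert sens == pytest.approx(16 / 23)
        assert spec == 1.0

    def test_female_70s_worked_example(self):
        acc, _, _ = mh.confusion_metrics(11, 9, 0, 20)
        assert acc == pytest.approx(31 / 40)

    def test_zero_denominator_reported_missing_not_zero(self):
        acc, sens, spec = mh.confusion_metrics(0, 0, 0, 10)
        assert acc == 1.0 and sens is None and spec == 1.0

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            mh.confusion_metrics(0, 0, 0, 0)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            mh.confusion_metrics(-1, 0, 0, 5)


class TestLeaveOnePatientOut:
    def test_one_fold_per_patient_one_prediction_per_record(self):
        table = toy_feature_table(n_per_class=2, records_per_patient=1, seed=1)
        # 3 patients / 5 records: give one patient an extra record
        table.record_ids.append("case_p0_r1")
        table.patient_ids.append("case_p0")
        table.labels.append("case")
        table.X = np.vstack([table.X, table.X[0] + 0.01])
        table = mh.FeatureTable(record_ids=table.record_ids[:5],
                                patient_ids=table.patient_ids[:5],
                                labels=table.labels[:5], X=table.X[:5],
                                feature_names=table.feature_names)
        result = mh.leave_one_patient_out_cv(table, mh.ModelConfig())
        assert len(result.predictions) == 5
        assert result.tp + result.fn + result.fp + result.tn == 5

    def test_separable_blobs_classified_perfectly(self):
        table = toy_feature_table(n_per_class=6, separation=50.0, seed=2)
        result = mh.leave_one_patient_out_cv(
            table, mh.ModelConfig(model="knn", knn_neighbors=1))
        assert result.accuracy == 1.0

    def test_no_leakage_between_records_of_one_patient(self):
        """Patients hold two identical records each; if a patient's own
        records leaked into training, 1-NN would score them perfectly.
        The geometry forces every held-out record's nearest other-patient
        neighbour to carry the wrong label, so correct LOPO scores 0."""
        X = np.array([[0.0], [0.0], [1.0], [1.0], [10.0], [10.0], [11.0], [11.0]])
        table = mh.FeatureTable(
            record_ids=[f"r{i}" for i in range(8)],
            patient_ids=["a", "a", "b", "b", "c", "c", "d", "d"],
            labels=["case", "case", "control", "control",
                    "case", "case", "control", "control"],
            X=X, feature_names=["f0"])
        result = mh.leave_one_patient_out_cv(
            table, mh.ModelConfig(knn_neighbors=1))
        assert result.accuracy == 0.0

    def test_matches_brute_force_one_nn_oracle(self):
        """Hand-rolled nearest-neighbour loop excluding the held-out patient."""
        for seed in range(5):
            table = toy_feature_table(n_per_class=5, separation=1.0, seed=seed,
                                      records_per_patient=1)
            result = mh.leave_one_patient_out_cv(
                table, mh.ModelConfig(knn_metric="euclidean", knn_neighbors=1))
            for i, rid in enumerate(table.record_ids):
                best, best_d = None, np.inf
                for j in range(len(table.record_ids)):
                    if table.patient_ids[j] == table.patient_ids[i]:
                        continue
                    d = np.linalg.norm(table.X[i] - table.X[j])
                    if d < best_d:
                        best, best_d = table.labels[j], d
                assert result.predictions[i] == best

    def test_balanced_table_accuracy_is_mean_of_sens_and_spec(self):
        for seed in (0, 3, 8):
            table = toy_feature_table(n_per_class=8, separation=0.8, seed=seed)
            result = mh.leave_one_patient_out_cv(
                table, mh.ModelConfig(knn_neighbors=3))
            assert result.accuracy == pytest.approx(
                (result.sensitivity + result.specificity) / 2)

    def test_single_class_table_rejected(self):
        table = toy_feature_table(n_per_class=3)
        table.labels = ["case"] * len(table.labels)
        with pytest.raises(ValueError, match="case and control"):
            mh.leave_one_patient_out_cv(table, mh.ModelConfig())

    def test_accuracy_monotone_in_effect_size(self):
        accs = []
        for sep in (0.0, 1.0, 3.0):
            table = toy_feature_table(n_per_class=15, separation=sep, seed=4)
            accs.append(mh.leave_one_patient_out_cv(
                table, mh.ModelConfig(knn_neighbors=1)).accuracy)
        assert accs[0] <= accs[1] <= accs[2]

    @pytest.mark.parametrize("metric", mh.KNN_METRICS)
    def test_every_table6_metric_runs(self, metric):
        table = toy_feature_table(n_per_class=4, separation=2.0, seed=6)
        result = mh.leave_one_patient_out_cv(
            table, mh.ModelConfig(knn_metric=metric, knn_neighbors=3))
        assert 0.0 <= result.accuracy <= 1.0

    def test_decision_tree_model(self):
        table = toy_feature_table(n_per_class=10, separation=3.0, seed=5)
        result = mh.leave_one_patient_out_cv(
            table, mh.ModelConfig(model="tree", tree_min_leaf=2, seed=1))
        assert result.accuracy > 0.8


class TestModelConfig:
    def test_even_neighbor_count_rejected(self):
        with pytest.raises(ValueError):
            mh.ModelConfig(knn_neighbors=4)

    def test_leaf_size_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            mh.ModelConfig(model="tree", tree_min_leaf=183)

    def test_unknown_metric_rejected(self):
        with pytest.raises(ValueError):
            mh.ModelConfig(knn_metric="mahalanobis")


class TestBayesianOptimize:
    def test_two_config_space_returns_exhaustive_winner(self):
        table = toy_feature_table(n_per_class=6, separation=1.5, seed=0)
        space = [mh.ModelConfig(knn_metric="euclidean", knn_neighbors=1),
                 mh.ModelConfig(knn_metric="euclidean", knn_neighbors=99)]
        result = mh.bayesian_optimize(table, space=space, seed=0)
        by_hand = {c: mh.leave_one_patient_out_cv(table, c).accuracy
                   for c in space}
        assert result.best_accuracy == max(by_hand.values())
        assert by_hand[result.best_config] == result.best_accuracy

    def test_separable_table_reaches_perfect_accuracy(self):
        table = toy_feature_table(n_per_class=5, separation=50.0, seed=1)
        result = mh.bayesian_optimize(table, model="tree", seed=2)
        assert result.best_accuracy == 1.0

    def test_deterministic_given_seed(self):
        table = toy_feature_table(n_per_class=5, separation=1.0, seed=3)
        a = mh.bayesian_optimize(table, model="knn", n_iterations=12, seed=7)
        b = mh.bayesian_optimize(table, model="knn", n_iterations=12, seed=7)
        assert a.best_config == b.best_config
        assert a.best_accuracy == b.best_accuracy
        assert a.n_evaluated == b.n_evaluated == 12

    def test_gp_surrogate_explores_large_space(self):
        table = toy_feature_table(n_per_class=5, separation=2.0, seed=4)
        result = mh.bayesian_optimize(table, model="knn", n_iterations=10,
                                      seed=1, exhaustive_limit=0)
        assert result.n_evaluated == 10
        assert result.best_accuracy >= 0.5

    def test_empty_table_rejected(self):
        table = toy_feature_table(n_per_class=2)
        empty = mh.FeatureTable(record_ids=[], patient_ids=[], labels=[],
                                X=np.empty((0, 4)),
                                feature_names=table.feature_names)
        with pytest.raises(ValueError, match="empty"):
            mh.bayesian_optimize(empty)


class TestConsensusHyperparameters:
    A = mh.ModelConfig(knn_metric="euclidean", knn_neighbors=3)
    B = mh.ModelConfig(knn_metric="cityblock", knn_neighbors=5)
    C = mh.ModelConfig(knn_metric="cosine", knn_neighbors=7)

    def test_mode_present_in_query_set(self):
        optima = [("I", 3, 1, [self.A]), ("II", 3, 1, [self.A]),
                  ("V6", 3, 1, [self.A, self.B])]
        assert mh.select_consensus_hyperparameters(optima, query=2) == self.A

    def test_mode_not_optimal_for_query_takes_first_entry(self):
        optima = [("I", 3, 1, [self.A]), ("II", 3, 1, [self.A]),
                  ("V6", 3, 1, [self.B])]
        assert mh.select_consensus_hyperparameters(optima, query=2) == self.B

    def test_single_combination(self):
        assert mh.select_consensus_hyperparameters(
            [("I", 3, 1, [self.C])]) == self.C


class TestDemographics:
    def make_table(self):
        table = toy_feature_table(n_per_class=3, seed=0)
        table.ages = [21.0, 40.0, 80.0, 33.0, 55.0, 62.0]
        table.sexes = ["male", "female", "male", "female", "male", "female"]
        return table

    def test_published_optimum_maps_youngest_to_age1_and_male_to_sex1(self):
        out = mh.append_demographics(self.make_table())
        age_col = out.X[:, -2]
        sex_col = out.X[:, -1]
        assert age_col[0] == pytest.approx(0.0103)            # youngest
        assert age_col[2] == pytest.approx(0.0103 + 0.9983)   # oldest
        assert sex_col[0] == pytest.approx(0.0486)            # male
        assert sex_col[1] == pytest.approx(0.0317)            # female

    def test_identity_params_give_plain_minmax_age(self):
        out = mh.append_demographics(
            self.make_table(),
            mh.DemographicNormalization(age1=0.0, age2=1.0))
        ages = np.array([21.0, 40.0, 80.0, 33.0, 55.0, 62.0])
        assert np.allclose(out.X[:, -2], (ages - 21) / (80 - 21))

    def test_missing_demographics_named_in_error(self):
        table = self.make_table()
        table.ages[3] = None
        with pytest.raises(ValueError, match=table.record_ids[3]):
            mh.append_demographics(table)


class TestStratifiedReport:
    def build(self, seed=0):
        table = toy_feature_table(n_per_class=12, separation=1.2, seed=seed)
        rng = np.random.default_rng(seed)
        table.ages = [float(a) for a in rng.integers(30, 90, len(table))]
        table.sexes = [("male" if i % 2 else "female") for i in range(len(table))]
        result = mh.leave_one_patient_out_cv(table, mh.ModelConfig(knn_neighbors=3))
        return table, result

    def test_band_accuracies_match_direct_recount(self):
        table, result = self.build()
        report = mh.stratified_report(result, table)
        correct = {r: t == p for r, t, p in zip(result.record_ids,
                                                result.truths,
                                                result.predictions)}
        for _, row in report.iterrows():
            if row["n"] == 0:
                assert np.isnan(row["accuracy"])
                continue
            picked = [
                correct[rid]
                for rid, age, sex in zip(table.record_ids, table.ages, table.sexes)
                if _in_band(row["age_band"], age)
                and (row["sex"] == "all" or sex == row["sex"])
            ]
            assert len(picked) == row["n"]
            assert row["accuracy"] == pytest.approx(np.mean(picked))

    def test_count_weighted_bands_pool_to_overall_accuracy(self):
        table, result = self.build(seed=5)
        report = mh.stratified_report(result, table)
        bands = report[(report.sex == "all") & (report.age_band != "all")]
        pooled = (bands.accuracy * bands.n).sum() / bands.n.sum()
        assert pooled == pytest.approx(result.accuracy)

    def test_all_records_in_one_stratum_equals_overall(self):
        table, result = self.build(seed=2)
        table.ages = [55.0] * len(table)
        report = mh.stratified_report(result, table)
        row = report[(report.age_band == "50-59") & (report.sex == "all")]
        assert row.iloc[0]["accuracy"] == pytest.approx(result.accuracy)


def _in_band(band, age):
    if band == "all":
        return True
    if band == "<50":
        return age < 50
    lo, hi = band.split("-")
    return float(lo) <= age <= float(hi)


class TestMisclassificationAnalysis:
    def test_twelve_of_sixteen_is_flagged(self):
        preds = {"rec": ["control"] * 12 + ["case"] * 4}
        truth = {"rec": "case"}
        flagged = mh.misclassification_analysis(preds, truth, threshold=0.75)
        assert flagged == {"rec": "false-negative"}

    def test_eleven_of_sixteen_is_not_flagged(self):
        preds = {"rec": ["control"] * 11 + ["case"] * 5}
        assert mh.misclassification_analysis(preds, {"rec": "case"}) == {}

    def test_flagged_control_tagged_false_positive(self):
        preds = {"rec": ["case"] * 10 + ["control"] * 2}
        flagged = mh.misclassification_analysis(preds, {"rec": "control"})
        assert flagged == {"rec": "false-positive"}

    def test_record_without_predictions_rejected(self):
        with pytest.raises(ValueError, match="no predictions"):
            mh.misclassification_analysis({"rec": []}, {"rec": "case"})
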