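import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from hsi_oncopipe import evaluation as ev
from hsi_oncopipe.errors import ContractError


class TestClassWeights:
    def test_imbalanced_formula(self):
        labels = np.array(["non_tumor"] * 75 + ["tumor"] * 25)
        w = ev.class_weights(labels)
        assert w["tumor"] == pytest.approx(2.0)
        assert w["non_tumor"] == pytest.approx(2 / 3)

    def test_balanced_identity(self):
        labels = np.array(["non_tumor"] * 50 + ["tumor"] * 50)
        assert ev.class_weights(labels) == {"non_tumor": 1.0, "tumor": 1.0}

    def test_missing_class_omitted_with_warning(self):
        with pytest.warns(UserWarning):
            w = ev.class_weights(np.array(["non_tumor"] * 5))
        assert "tumor" not in w

    def test_weighting_equals_duplication(self, rng):
        """Training with class weight k on the minority equals duplicating
        each minority point k times at uniform weight."""
        X_min = rng.normal([1.5, 1.0], 0.8, (5, 2))
        X_maj = rng.normal([-1.0, -0.5], 0.8, (15, 2))
        X = np.vstack([X_maj, X_min])
        y = np.array(["non_tumor"] * 15 + ["tumor"] * 5)
        weighted = ev.fit_linear_svm(X, y, {"non_tumor": 1.0, "tumor": 3.0}, C=1.0)
        X_dup = np.vstack([X_maj, np.repeat(X_min, 3, axis=0)])
        y_dup = np.array(["non_tumor"] * 15 + ["tumor"] * 15)
        duplicated = ev.fit_linear_svm(
            X_dup, y_dup, {"non_tumor": 1.0, "tumor": 1.0}, C=1.0
        )
        probe = rng.normal(0, 1.5, (20, 2))
        np.testing.assert_allclose(
            weighted.decision(probe), duplicated.decision(probe), atol=1e-4
        )


def hinge_objective(params, X, y_signed, sample_weight, C):
    w, b = params[:-1], params[-1]
    margins = y_signed * (X @ w + b)
    hinge = np.maximum(0.0, 1.0 - margins)
    return 0.5 * np.dot(w, w) + C * np.sum(sample_weight * hinge)


class TestFitLinearSvm:
    def test_separable_training_accuracy(self, rng):
        X = np.vstack([rng.normal([3, 3], 0.3, (20, 2)), rng.normal([-3, -3], 0.3, (20, 2))])
        y = np.array(["tumor"] * 20 + ["non_tumor"] * 20)
        model = ev.fit_linear_svm(X, y)
        pred = model.decision(X) > 0
        assert np.array_equal(pred, y == "tumor")

    def test_symmetric_two_point_problem(self):
        X = np.array([[-1.0], [1.0]])
        y = np.array(["non_tumor", "tumor"])
        model = ev.fit_linear_svm(X, y, {"non_tumor": 1.0, "tumor": 1.0})
        assert model.weights[0] > 0
        assert model.bias == pytest.approx(0.0, abs=1e-9)

    def test_objective_matches_numeric_minimizer(self, rng):
        """Six-point problem: libsvm's solution attains the same primal
        hinge objective as a direct numeric minimization."""
        X = np.array([[0.0, 0.0], [1.0, 0.5], [0.5, 1.0], [2.0, 2.0], [2.5, 1.5], [1.5, 2.5]])
        y = np.array(["non_tumor"] * 3 + ["tumor"] * 3)
        y_signed = np.where(y == "tumor", 1.0, -1.0)
        wts = {"non_tumor": 1.0, "tumor": 1.0}
        C = 1.0
        model = ev.fit_linear_svm(X, y, wts, C=C)
        sw = np.ones(len(y))
        ours = hinge_objective(
            np.append(model.weights, model.bias), X, y_signed, sw, C
        )
        best = np.inf
        for x0 in [np.zeros(3), np.append(model.weights, model.bias), rng.normal(0, 1, 3)]:
            res = minimize(
                hinge_objective, x0, args=(X, y_signed, sw, C),
                method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000},
            )
            best = min(best, res.fun)
        assert ours == pytest.approx(best, abs=1e-6)

    def test_single_class_rejected(self):
        with pytest.raises(ContractError):
            ev.fit_linear_svm(np.ones((4, 2)), np.array(["tumor"] * 4))

    def test_degenerate_rows_rejected(self):
        X = np.ones((6, 2))
        y = np.array(["tumor"] * 3 + ["non_tumor"] * 3)
        with pytest.raises(ContractError):
            ev.fit_linear_svm(X, y)


def labels_arr(*pairs):
    return np.array(list(pairs))


class TestRocPoints:
    def test_perfect_ranking_passes_corner(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = labels_arr("tumor", "tumor", "non_tumor", "non_tumor")
        roc = ev.roc_points(scores, labels)
        assert ((roc["fpr"] == 0) & (roc["tpr"] == 1)).any()
        assert roc.iloc[0]["fpr"] == 0 and roc.iloc[0]["tpr"] == 0
        assert roc.iloc[-1]["fpr"] == 1 and roc.iloc[-1]["tpr"] == 1

    def test_reversed_ranking_auc_zero(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        labels = labels_arr("tumor", "tumor", "non_tumor", "non_tumor")
        roc = ev.roc_points(scores, labels)
        assert ((roc["fpr"] == 1) & (roc["tpr"] == 0)).any()
        assert ev.auc(roc) == 0.0

    def test_tied_scores_collapse(self):
        scores = np.array([0.5, 0.5, 0.5, 0.3, 0.3, 0.1])
        labels = labels_arr("tumor", "non_tumor", "tumor", "non_tumor", "tumor", "non_tumor")
        roc = ev.roc_points(scores, labels)
        # thresholds: inf, 0.5, 0.3, 0.1 -> 4 points
        assert len(roc) == 4
        assert roc["fpr"].is_monotonic_increasing
        assert roc["tpr"].is_monotonic_increasing

    def test_single_class_rejected(self):
        with pytest.raises(ContractError):
            ev.roc_points(np.array([1.0, 2.0]), labels_arr("tumor", "tumor"))


def auc_pair_oracle(scores, labels):
    pos = scores[labels == "tumor"]
    neg = scores[labels == "non_tumor"]
    wins = ties = 0
    for p, n in itertools.product(pos, neg):
        wins += p > n
        ties += p == n
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestAuc:
    def test_perfect(self):
        roc = ev.roc_points(
            np.array([3.0, 2.0, 1.0, 0.0]),
            labels_arr("tumor", "tumor", "non_tumor", "non_tumor"),
        )
        assert ev.auc(roc) == 1.0

    def test_all_equal_scores_half(self):
        roc = ev.roc_points(
            np.zeros(6),
            labels_arr("tumor", "tumor", "tumor", "non_tumor", "non_tumor", "non_tumor"),
        )
        assert ev.auc(roc) == pytest.approx(0.5)

    def test_matches_pair_oracle_with_ties(self, rng):
        for _ in range(20):
            n = int(rng.integers(6, 30))
            scores = np.round(rng.normal(0, 1, n), 1)
            labels = np.where(rng.random(n) < 0.4, "tumor", "non_tumor")
            if len(set(labels)) < 2:
                continue
            roc = ev.roc_points(scores, labels)
            assert ev.auc(roc) == pytest.approx(auc_pair_oracle(scores, labels), abs=1e-12)


class TestYouden:
    def test_enumerated_maximum(self):
        scores = np.array([0.9, 0.8, 0.7, 0.6, 0.2])
        labels = np.array(["tumor", "tumor", "non_tumor", "tumor", "non_tumor"])
        roc = ev.roc_points(scores, labels)
        j = roc["tpr"] - roc["fpr"]
        best_rows = roc[j == j.max()]
        expected = float(best_rows.sort_values("fpr").iloc[0]["threshold"])
        assert ev.youden_threshold(roc) == expected

    def test_exhaustive_oracle_random(self, rng):
        for _ in range(20):
            n = int(rng.integers(6, 40))
            scores = np.round(rng.normal(0, 1, n), 1)
            labels = np.where(rng.random(n) < 0.5, "tumor", "non_tumor")
            if len(set(labels)) < 2:
                continue
            roc = ev.roc_points(scores, labels)
            j = (roc["tpr"] - roc["fpr"]).to_numpy()
            candidates = roc[np.isclose(j, j.max())].sort_values("fpr")
            assert ev.youden_threshold(roc) == float(candidates.iloc[0]["threshold"])

    def test_perfect_classifier_j_one(self):
        roc = ev.roc_points(
            np.array([2.0, 1.0, -1.0, -2.0]),
            labels_arr("tumor", "tumor", "non_tumor", "non_tumor"),
        )
        t = ev.youden_threshold(roc)
        pred_row = roc[roc["threshold"] == t].iloc[0]
        assert pred_row["tpr"] - pred_row["fpr"] == 1.0

    def test_uninformative_tie_picks_lowest_fpr(self):
        roc = ev.roc_points(
            np.zeros(4), labels_arr("tumor", "non_tumor", "tumor", "non_tumor")
        )
        assert ev.youden_threshold(roc) == np.inf  # the (0, 0) endpoint


class TestMetrics:
    def test_symmetric_quarters(self):
        vals = ev.metrics(ev.ConfusionMatrix(25, 25, 25, 25))
        for m in ("sensitivity", "specificity", "ppv", "npv"):
            assert vals[m] == pytest.approx(0.5)
        assert vals["mcc"] == pytest.approx(0.0)

    def test_perfect_matrix(self):
        vals = ev.metrics(ev.ConfusionMatrix(10, 0, 12, 0))
        for m in ("sensitivity", "specificity", "ppv", "npv", "mcc"):
            assert vals[m] == pytest.approx(1.0)

    def test_worked_arithmetic_example(self):
        vals = ev.metrics(ev.ConfusionMatrix(tp=40, fn=10, tn=30, fp=20))
        assert vals["mcc"] == pytest.approx(1000 / math.sqrt(60 * 50 * 50 * 40))
        assert vals["sensitivity"] == pytest.approx(0.8)
        assert vals["specificity"] == pytest.approx(0.6)

    def test_zero_denominators_undefined(self):
        vals = ev.metrics(ev.ConfusionMatrix(tp=0, fp=0, tn=5, fn=0))
        assert vals["sensitivity"] is None
        assert vals["ppv"] is None
        assert vals["mcc"] is None
        assert vals["specificity"] == 1.0
        assert vals["npv"] == 1.0

    def test_direct_arithmetic_oracle_random(self, rng):
        for _ in range(200):
            tp, fp, tn, fn = (int(v) for v in rng.integers(0, 50, 4))
            vals = ev.metrics(ev.ConfusionMatrix(tp, fp, tn, fn))
            if tp + fn:
                assert vals["sensitivity"] == pytest.approx(tp / (tp + fn))
            if tn + fp:
                assert vals["specificity"] == pytest.approx(tn / (tn + fp))
            if vals["mcc"] is not None:
                assert -1.0 <= vals["mcc"] <= 1.0
                num = tp * tn - fp * fn
                den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
                assert vals["mcc"] == pytest.approx(num / den)

    def test_mcc_zero_on_proportional_rows(self):
        # rows (TP, FN) and (FP, TN) proportional -> MCC 0
        vals = ev.metrics(ev.ConfusionMatrix(tp=10, fn=20, fp=5, tn=10))
        assert vals["mcc"] == pytest.approx(0.0, abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ContractError):
            ev.ConfusionMatrix(-1, 0, 0, 0)


def make_result(pid, values, n_tumor=10, n_non=10):
    cm = ev.ConfusionMatrix(1, 1, 1, 1)
    vals = dict.fromkeys(ev.METRIC_NAMES)
    vals.update(values)
    return ev.PatientResult(pid, n_tumor, n_non, cm, 0.0, vals)


class TestAggregateMean:
    def test_single_patient_identity(self):
        row = make_result("P1", {"sensitivity": 0.7, "specificity": 0.6})
        report = ev.aggregate_mean([row])
        assert report.mean["sensitivity"] == pytest.approx(0.7)
        assert report.mean["specificity"] == pytest.approx(0.6)
        assert report.mean["auc"] is None

    def test_tumor_free_patients_count_only_for_specificity(self):
        rows = [
            make_result("P1", {"sensitivity": 0.8, "specificity": 0.6, "ppv": 0.5}),
            make_result(
                "P2", {"specificity": 1.0, "ppv": 0.0, "npv": 1.0}, n_tumor=0
            ),
        ]
        report = ev.aggregate_mean(rows)
        assert report.mean["sensitivity"] == pytest.approx(0.8)
        assert report.mean["specificity"] == pytest.approx(0.8)
        assert report.mean["ppv"] == pytest.approx(0.5)  # P2's PPV excluded
        assert report.mean["npv"] is None  # only tumor-free NPV available

    def test_rounding_half_up(self):
        assert ev.round2(0.805) == 0.81
        assert ev.round2(0.825) == 0.83
        assert ev.round2(0.8449) == 0.84


def synthetic_feature_frame(rng, n_patients=4, n_per=40, separation=3.0,
                            tumor_free=()):
    rows = []
    for p in range(n_patients):
        pid = f"P{p + 1}"
        for i in range(n_per):
            is_tumor = (i % 2 == 0) and pid not in tumor_free
            mu = separation if is_tumor else 0.0
            rows.append({
                "patient_id": pid,
                "sample_id": "S1",
                "label": "tumor" if is_tumor else "non_tumor",
                "f1": rng.normal(mu, 1.0),
                "f2": rng.normal(-mu, 1.0),
            })
    return pd.DataFrame(rows)


class TestLopoCv:
    def test_separable_cohort_perfect(self, rng):
        df = synthetic_feature_frame(rng, n_patients=3, separation=8.0)
        report = ev.lopo_cv(df)
        for row in report.rows:
            assert row.values["auc"] == pytest.approx(1.0)
            assert row.values["sensitivity"] == pytest.approx(1.0)
            assert row.values["specificity"] == pytest.approx(1.0)

    def test_tumor_free_patient_dash_semantics(self, rng):
        df = synthetic_feature_frame(rng, n_patients=3, tumor_free=("P2",))
        report = ev.lopo_cv(df)
        row = next(r for r in report.rows if r.patient_id == "P2")
        assert not row.has_tumor
        assert row.values["specificity"] is not None
        assert row.values["sensitivity"] is None
        assert row.values["auc"] is None

    def test_deterministic(self, rng):
        df = synthetic_feature_frame(rng, separation=1.0)
        a = ev.lopo_cv(df).to_dataframe()
        b = ev.lopo_cv(df).to_dataframe()
        pd.testing.assert_frame_equal(a, b)

    def test_null_separation_auc_near_half(self):
        aucs = []
        for seed in range(12):
            rng = np.random.default_rng(seed)
            df = synthetic_feature_frame(rng, n_patients=4, n_per=60, separation=0.0)
            report = ev.lopo_cv(df)
            aucs.extend(r.values["auc"] for r in report.rows if r.values["auc"] is not None)
        assert abs(np.mean(aucs) - 0.5) < 0.06

    def test_single_patient_rejected(self, rng):
        df = synthetic_feature_frame(rng, n_patients=1)
        with pytest.raises(ContractError):
            ev.lopo_cv(df)

    def test_single_class_training_fold_recorded(self, rng):
        df = synthetic_feature_frame(rng, n_patients=2, tumor_free=("P1",))
        report = ev.lopo_cv(df)
        # holding out P1 leaves only P2 (has both classes) -> trains fine;
        # holding out P2 leaves P1 (single class) -> skipped with error
        assert len(report.fold_errors) == 1
        assert "P2" in report.fold_errors[0]

    def test_report_serialization(self, rng, tmp_path):
        df = synthetic_feature_frame(rng)
        report = ev.lopo_cv(df)
        report.to_csv(tmp_path / "r.csv")
        report.to_json(tmp_path / "r.json")
        back = pd.read_csv(tmp_path / "r.csv")
        assert list(back["patient"])[-1] == "Mean"
        import json

        payload = json.loads((tmp_path / "r.json").read_text())
        assert len(payload["patients"]) == len(report.rows)
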