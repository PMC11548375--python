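import numpy as np
import pytest

from conftest import make_toy_epochs
from nirsleep.cohort import (
    EPOCH_COUNTS,
    FIXTURE_FOLD_PLAN,
    STUDY_COHORT,
    binary_task_epoch_total,
    fold_duration_min,
)
from nirsleep.evaluation import (
    classification_metrics,
    confusion_counts,
    make_folds,
    pma_sensitivity,
    run_cross_validation,
    vitals_agreement,
    FoldPlan,
)
from nirsleep.models import TrainedModel


def oracle_metrics(tn, fp, fn, tp):
    """Closed-form metric oracle from a confusion matrix (QS positive)."""
    n = tn + fp + fn + tp
    acc = (tp + tn) / n
    recall_pos = tp / (tp + fn) if tp + fn else np.nan
    recall_neg = tn / (tn + fp) if tn + fp else np.nan
    bal = (recall_pos + recall_neg) / 2
    prec = tp / (tp + fp) if tp + fp else 0.0
    f1 = (2 * prec * recall_pos / (prec + recall_pos)
          if prec + recall_pos > 0 else 0.0)
    pe = ((tp + fp) * (tp + fn) + (tn + fn) * (tn + fp)) / n**2
    kappa = (acc - pe) / (1 - pe) if pe != 1 else 0.0
    return acc, bal, f1, kappa


def labels_from_confusion(tn, fp, fn, tp):
    y = np.array([0] * (tn + fp) + [1] * (fn + tp))
    p = np.array([0.0] * tn + [1.0] * fp + [0.0] * fn + [1.0] * tp)
    return y, p


class TestFoldPlanFixtures:
    def test_fixture_fold_durations_match_published(self):
        plan = make_folds(STUDY_COHORT, "leave_measurement_out_5fold", use_fixture=True)
        durations = {tuple(f): fold_duration_min(tuple(f)) for f in plan.assignment}
        assert durations[("2", "9")] == 78.0
        assert durations[("4a", "4b")] == 112.0
        assert durations[("1", "3")] == 149.0
        assert durations[("7", "8")] == 131.0
        assert durations[("5", "6")] == 253.0

    def test_each_subject_in_exactly_one_fold(self):
        plan = make_folds(STUDY_COHORT, "leave_measurement_out_5fold", use_fixture=True)
        by_id = {m.measurement_id: m.subject_id for m in STUDY_COHORT}
        seen = {}
        for k, fold in enumerate(plan.assignment):
            for mid in fold:
                subj = by_id[mid]
                assert seen.setdefault(subj, k) == k
        flat = sorted(m for f in plan.assignment for m in f)
        assert flat == sorted(by_id)

    def test_searched_plan_is_subject_exclusive_partition(self):
        plan = make_folds(STUDY_COHORT, "leave_measurement_out_5fold", seed=0)
        by_id = {m.measurement_id: m.subject_id for m in STUDY_COHORT}
        assert sorted(m for f in plan.assignment for m in f) == sorted(by_id)
        for fold in plan.assignment:
            assert len(fold) == 2
        # subject 4's two measurements must share a fold
        fold_of = {m: k for k, f in enumerate(plan.assignment) for m in f}
        assert fold_of["4a"] == fold_of["4b"]

    def test_searched_plan_minimizes_ratio_spread_vs_random(self):
        plan = make_folds(STUDY_COHORT, "leave_measurement_out_5fold", seed=0)
        ratio = {m.measurement_id: m.qs_as_ratio for m in STUDY_COHORT}
        spread = lambda p: (max(np.mean([ratio[m] for m in f]) for f in p)
                            - min(np.mean([ratio[m] for m in f]) for f in p))
        assert spread(plan.assignment) <= spread(FIXTURE_FOLD_PLAN)

    def test_pooled_scheme_is_stratified_partition(self):
        labels = np.array(["AS"] * 70 + ["QS"] * 30)
        plan = make_folds(None, "pooled_10fold", seed=1, labels=labels)
        flat = sorted(i for f in plan.assignment for i in f)
        assert flat == list(range(100))
        for f in plan.assignment:
            assert sum(labels[i] == "QS" for i in f) == 3

    def test_epoch_bookkeeping_723(self):
        assert binary_task_epoch_total() == 723
        assert EPOCH_COUNTS["QS"] + EPOCH_COUNTS["AS"] + EPOCH_COUNTS["Wake"] == 761


class TestClassificationMetrics:
    def test_perfect_predictions_all_hundred(self):
        y = np.array([0, 0, 1, 1])
        m = classification_metrics(y, np.array([0.1, 0.2, 0.9, 0.8]))
        for k in ("accuracy", "balanced_accuracy", "f1", "kappa", "auc_roc"):
            assert m[k] == pytest.approx(100.0)

    def test_all_qs_predictor_on_quarter_qs_set(self):
        y = np.array([1] * 25 + [0] * 75)
        m = classification_metrics(y, np.full(100, 0.9))
        assert m["accuracy"] == pytest.approx(25.0)
        assert m["balanced_accuracy"] == pytest.approx(50.0)
        assert m["kappa"] == pytest.approx(0.0)

    def test_worked_confusion_example(self):
        # TP=40 FN=10 FP=20 TN=130
        y, p = labels_from_confusion(tn=130, fp=20, fn=10, tp=40)
        m = classification_metrics(y, p)
        acc, bal, f1, kappa = oracle_metrics(130, 20, 10, 40)
        assert m["accuracy"] == pytest.approx(100 * acc)  # 85%
        assert m["accuracy"] == pytest.approx(85.0)
        assert m["balanced_accuracy"] == pytest.approx(100 * bal)
        assert m["f1"] == pytest.approx(100 * f1)
        assert m["kappa"] == pytest.approx(100 * kappa)

    def test_single_class_auc_flagged_missing(self):
        m = classification_metrics(np.ones(5, dtype=int), np.linspace(0.1, 0.9, 5))
        assert np.isnan(m["auc_roc"])

    def test_brute_force_oracle_on_random_confusions(self):
        """200 random confusion matrices against the closed-form oracle."""
        rng = np.random.default_rng(0)
        for _ in range(200):
            tn, fp, fn, tp = rng.integers(1, 60, 4)
            y, p = labels_from_confusion(int(tn), int(fp), int(fn), int(tp))
            m = classification_metrics(y, p)
            acc, bal, f1, kappa = oracle_metrics(int(tn), int(fp), int(fn), int(tp))
            assert abs(m["accuracy"] - 100 * acc) < 1e-12 * 100 + 1e-9
            assert abs(m["balanced_accuracy"] - 100 * bal) < 1e-9
            assert abs(m["f1"] - 100 * f1) < 1e-9
            assert abs(m["kappa"] - 100 * kappa) < 1e-9

    def test_auc_matches_mann_whitney_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            y = rng.integers(0, 2, 40)
            if len(set(y)) < 2:
                continue
            p = rng.random(40)
            m = classification_metrics(y, p)
            pos, neg = p[y == 1], p[y == 0]
            wins = sum((pp > nn) + 0.5 * (pp == nn) for pp in pos for nn in neg)
            assert m["auc_roc"] == pytest.approx(100 * wins / (len(pos) * len(neg)),
                                                 abs=1e-9)

    def test_kappa_never_exceeds_accuracy_per_confusion(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            tn, fp, fn, tp = rng.integers(0, 50, 4)
            if tn + fp == 0 or fn + tp == 0 or (tn + fp + fn + tp) == 0:
                continue
            y, p = labels_from_confusion(int(tn), int(fp), int(fn), int(tp))
            m = classification_metrics(y, p)
            assert m["kappa"] <= m["accuracy"] + 1e-9

    def test_confusion_counts_sum(self):
        y = np.array([0, 1, 1, 0, 1])
        pred = np.array([0, 1, 0, 1, 1])
        c = confusion_counts(y, pred)
        assert c.sum() == 5
        assert c[1, 1] == 2  # TP


class TestVitalsAgreement:
    def test_identical_series(self):
        x = np.linspace(100, 150, 50)
        a = vitals_agreement(x, x)
        assert a.me == 0 and a.rmse == 0 and a.loa == 0

    def test_constant_offset(self):
        x = np.linspace(100, 150, 50)
        a = vitals_agreement(x + 2.0, x)
        assert a.me == pytest.approx(2.0)
        assert a.rmse == pytest.approx(2.0)
        assert a.loa == pytest.approx(0.0, abs=1e-9)
        assert a.pearson_r == pytest.approx(100.0)

    def test_brute_force_formula_oracle(self):
        rng = np.random.default_rng(3)
        ext = rng.normal(140, 10, 100)
        ref = ext + rng.normal(0, 2, 100)
        a = vitals_agreement(ext, ref)
        d = [ext[i] - ref[i] for i in range(100)]
        me = sum(d) / 100
        rmse = (sum(x * x for x in d) / 100) ** 0.5
        sd = (sum((x - me) ** 2 for x in d) / 99) ** 0.5
        assert a.me == pytest.approx(me, abs=1e-12)
        assert a.rmse == pytest.approx(rmse, abs=1e-12)
        assert a.loa == pytest.approx(1.96 * sd, abs=1e-12)
        assert a.rmse >= abs(a.me)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            vitals_agreement(np.zeros(2), np.zeros(2))


class StubModel(TrainedModel):
    """Always predicts QS with probability 0.9."""

    def __init__(self):
        super().__init__(model_id="stub", estimator=None)

    def predict_proba(self, epochs):
        return np.full(len(epochs), 0.9)


class TestRunCrossValidation:
    def make_plan(self, epochs, n=4):
        idx = np.arange(len(epochs))
        return FoldPlan(scheme="pooled_10fold",
                        assignment=[list(map(int, f)) for f in np.array_split(idx, n)])

    def test_stub_model_matches_closed_form(self):
        epochs = make_toy_epochs(20)
        plan = self.make_plan(epochs)
        report = run_cross_validation(
            epochs, plan, {"stub": lambda tr, w, k: StubModel()})
        for k, fold_idx in enumerate(plan.assignment):
            y = np.array([1 if epochs[i].label == "QS" else 0 for i in fold_idx])
            expected = 100.0 * y.mean()
            assert report.per_fold["stub"][k]["accuracy"] == pytest.approx(expected)

    def test_two_identical_models_identical_reports(self):
        from nirsleep.evaluation import benchmark_factory
        from nirsleep.models import BenchmarkSpec
        epochs = make_toy_epochs(15, separation=2.0)
        plan = self.make_plan(epochs, n=3)
        f1 = benchmark_factory(BenchmarkSpec(classifier_id="RF", seed=5))
        f2 = benchmark_factory(BenchmarkSpec(classifier_id="RF", seed=5))
        report = run_cross_validation(epochs, plan, {"a": f1, "b": f2})
        for fa, fb in zip(report.per_fold["a"], report.per_fold["b"]):
            for k in fa:
                assert fa[k] == fb[k] or (np.isnan(fa[k]) and np.isnan(fb[k]))

    def test_incomplete_plan_rejected(self):
        epochs = make_toy_epochs(10)
        plan = FoldPlan(scheme="pooled_10fold", assignment=[[0, 1], [2, 3]])
        with pytest.raises(ValueError, match="cover"):
            run_cross_validation(epochs, plan, {"stub": lambda tr, w, k: StubModel()})

    def test_summary_shape(self):
        epochs = make_toy_epochs(20)
        plan = self.make_plan(epochs)
        report = run_cross_validation(epochs, plan,
                                      {"stub": lambda tr, w, k: StubModel()})
        summary = report.summary()
        assert set(summary["stub"]) == {"accuracy", "balanced_accuracy", "f1",
                                        "kappa", "auc_roc"}


class FixedPerformanceModel(TrainedModel):
    """Predicts labels correctly with a per-recording accuracy dialed in."""

    def __init__(self, acc_by_recording):
        super().__init__(model_id="fixed", estimator=None)
        self.acc = acc_by_recording

    def predict_proba(self, epochs):
        out = []
        for i, e in enumerate(epochs):
            correct = (i / max(1, len(epochs) - 1)) < self.acc.get(e.recording_id, 0.5)
            truth = 1.0 if e.label == "QS" else 0.0
            out.append(truth if correct else 1.0 - truth)
        return np.array(out)


class TestPmaSensitivity:
    def make_cohort(self, n_subj=5, pma0=30.0):
        from nirsleep.cohort import RecordingManifest
        epochs, meta = [], []
        for i in range(n_subj):
            rid = f"m{i + 1}"
            epochs.extend(make_toy_epochs(6, separation=0.0, seed=i))
            for e in epochs[-12:]:
                e.recording_id = rid
                e.subject_id = f"s{i + 1}"
            meta.append(RecordingManifest(
                subject_id=f"s{i + 1}", measurement_id=rid, ga_weeks=28.0,
                pma_weeks=pma0 + i, sex="F", birthweight_g=1000,
                duration_min=30.0, qs_as_ratio=1.0))
        return epochs, meta

    def test_identity_performance_gives_r_100(self):
        epochs, meta = self.make_cohort()
        acc = {m.measurement_id: 0.5 + 0.08 * i for i, m in enumerate(meta)}
        res = pma_sensitivity(epochs, meta,
                              lambda tr, w, k: FixedPerformanceModel(acc),
                              metric="accuracy", n_boot=1, seed=0)
        assert res["r_mean"] == pytest.approx(100.0, abs=1e-6)

    def test_nboot_one_equals_plain_estimate(self):
        epochs, meta = self.make_cohort()
        acc = {m.measurement_id: 0.5 + 0.08 * i for i, m in enumerate(meta)}
        factory = lambda tr, w, k: FixedPerformanceModel(acc)
        r1 = pma_sensitivity(epochs, meta, factory, n_boot=1, seed=0)
        assert len(r1["per_boot_r"]) == 1
        assert r1["r_sd"] == 0.0

    def test_null_simulation_small_r(self):
        from nirsleep.evaluation import benchmark_factory
        from nirsleep.models import BenchmarkSpec
        epochs, meta = self.make_cohort(n_subj=6)
        res = pma_sensitivity(epochs, meta,
                              benchmark_factory(BenchmarkSpec(classifier_id="NB")),
                              n_boot=2, seed=1)
        assert abs(res["r_mean"]) < 90.0  # no systematic PMA relation

    def test_fewer_than_three_subjects_rejected(self):
        epochs, meta = self.make_cohort(n_subj=2)
        with pytest.raises(ValueError, match="3 subjects"):
            pma_sensitivity(epochs, meta, lambda tr, w, k: StubModel())
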