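"""Cross-validation orchestration, classification metrics, vitals agreement,
and the PMA sensitivity analysis.

Metrics are reported as percentages with QS as the positive class. The
leave-measurement-out planner searches perfect pairings of measurements into
five two-measurement folds (subject-exclusive) that minimize the spread of
per-fold QS/AS ratios; the published grouping ships as a fixture plan.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import (
    accuracy_score,
    balanced_accuracy_score,
    cohen_kappa_score,
    f1_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold

from .cohort import FIXTURE_FOLD_PLAN, RecordingManifest
from .models import (
    BenchmarkSpec,
    ClassWeights,
    TrainedModel,
    train_benchmark,
    train_cnn,
)
from .types import FeatureEpoch

METRIC_NAMES = ("accuracy", "balanced_accuracy", "f1", "kappa", "auc_roc")


@dataclass
class FoldPlan:
    """Partition of epochs (pooled) or measurements (measurement-out) into folds."""

    scheme: str  # pooled_10fold | leave_measurement_out_5fold | leave_one_subject_out
    assignment: list[list[int]] | list[list[str]]  # per fold: epoch idx or measurement ids
    seed: int = 0

    def n_folds(self) -> int:
        return len(self.assignment)


@dataclass
class AgreementStats:
    """Extracted-vs-reference agreement: ME, RMSE, LoA half-width, Pearson r (%)."""

    me: float
    rmse: float
    loa: float
    pearson_r: float


@dataclass
class EvalReport:
    """Per-fold metric table (%) with mean +/- sd summaries per model."""

    scheme: str
    per_fold: dict[str, list[dict[str, float]]] = field(default_factory=dict)
    confusions: dict[str, list[np.ndarray]] = field(default_factory=dict)

    def summary(self) -> dict[str, dict[str, tuple[float, float]]]:
        out: dict[str, dict[str, tuple[float, float]]] = {}
        for model, folds in self.per_fold.items():
            out[model] = {}
            for m in METRIC_NAMES:
                vals = [f[m] for f in folds if np.isfinite(f[m])]
                out[model][m] = (float(np.mean(vals)), float(np.std(vals, ddof=1))
                                 if len(vals) > 1 else 0.0) if vals else (np.nan, np.nan)
        return out


def classification_metrics(y_true: np.ndarray, probs: np.ndarray,
                           threshold: float = 0.5) -> dict[str, float]:
    """Accuracy, balanced accuracy, F1 (QS positive), kappa, AUC — all %.

    Hard labels via ``prob > threshold`` (exactly 0.5 is negative). AUC is
    NaN (flagged missing) when the evaluation set has a single class.
    """
    y_true = np.asarray(y_true, dtype=int)
    probs = np.asarray(probs, dtype=float)
    y_pred = (probs > threshold).astype(int)
    out = {
        "accuracy": 100.0 * accuracy_score(y_true, y_pred),
        "balanced_accuracy": 100.0 * balanced_accuracy_score(y_true, y_pred),
        "f1": 100.0 * f1_score(y_true, y_pred, pos_label=1, zero_division=0),
        "kappa": 100.0 * cohen_kappa_score(y_true, y_pred),
    }
    if len(np.unique(y_true)) < 2:
        out["auc_roc"] = float("nan")
    else:
        out["auc_roc"] = 100.0 * roc_auc_score(y_true, probs)  # rank/Mann-Whitney AUC
    return out


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray) -> np.ndarray:
    """2x2 confusion matrix [[TN, FP], [FN, TP]] with QS = 1 positive."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    m = np.zeros((2, 2), dtype=int)
    for t, p in ((0, 0), (0, 1), (1, 0), (1, 1)):
        m[t, p] = int(np.sum((y_true == t) & (y_pred == p)))
    return m


def vitals_agreement(extracted: np.ndarray, reference: np.ndarray) -> AgreementStats:
    """ME/RMSE/LoA/Pearson between aligned extracted and reference series.

    LoA is the Bland-Altman half-width 1.96 * sd of the paired differences.
    """
    extracted = np.asarray(extracted, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if extracted.shape != reference.shape or len(extracted) < 3:
        raise ValueError("need at least 3 aligned (extracted, reference) points")
    d = extracted - reference
    me = float(np.mean(d))
    rmse = float(np.sqrt(np.mean(d**2)))
    loa = float(1.96 * np.std(d, ddof=1))
    if np.std(extracted) == 0 or np.std(reference) == 0:
        r = float("nan")
    else:
        r = float(100.0 * stats.pearsonr(extracted, reference)[0])
    return AgreementStats(me=me, rmse=rmse, loa=loa, pearson_r=r)


def align_to_reference(times_1hz: np.ndarray, values_1hz: np.ndarray,
                       ref_times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sample the 1 Hz extracted series at the 0.4 Hz reference timestamps
    (interior points only, no extrapolation)."""
    sel = (ref_times >= times_1hz[0]) & (ref_times <= times_1hz[-1])
    return np.interp(ref_times[sel], times_1hz, values_1hz), sel


# ---------------------------------------------------------------------------
# fold planning


def make_folds(
    meta: Sequence[RecordingManifest] | None,
    scheme: str,
    seed: int = 0,
    labels: np.ndarray | None = None,
    use_fixture: bool = False,
) -> FoldPlan:
    """Build a fold plan.

    pooled_10fold: epoch-level stratified 10-fold (requires ``labels``).
    leave_measurement_out_5fold: pairs of measurements, subject-exclusive,
    minimizing the range of per-fold QS/AS ratios; ``use_fixture=True``
    returns the published grouping instead of searching.
    leave_one_subject_out: one fold per subject.
    """
    if scheme == "pooled_10fold":
        if labels is None:
            raise ValueError("pooled scheme needs epoch labels for stratification")
        y = np.asarray(labels)
        skf = StratifiedKFold(n_splits=10, shuffle=True, random_state=seed)
        assignment = [test.tolist() for _, test in skf.split(np.zeros(len(y)), y)]
        return FoldPlan(scheme=scheme, assignment=assignment, seed=seed)

    if meta is None:
        raise ValueError("measurement-out schemes need per-measurement metadata")

    if scheme == "leave_one_subject_out":
        subjects: dict[str, list[str]] = {}
        for m in meta:
            subjects.setdefault(m.subject_id, []).append(m.measurement_id)
        assignment = [sorted(v) for _, v in sorted(subjects.items())]
        return FoldPlan(scheme=scheme, assignment=assignment, seed=seed)

    if scheme != "leave_measurement_out_5fold":
        raise ValueError(f"unknown CV scheme {scheme!r}")

    if use_fixture:
        return FoldPlan(scheme=scheme, assignment=[list(f) for f in FIXTURE_FOLD_PLAN],
                        seed=seed)
    if len(meta) < 10:
        raise ValueError("the 5-fold measurement-out scheme needs >= 10 measurements")

    ids = [m.measurement_id for m in meta]
    ratio = {m.measurement_id: m.qs_as_ratio for m in meta}
    subj = {m.measurement_id: m.subject_id for m in meta}
    # multi-measurement subjects are glued into one fold up front
    forced = {}
    for m in meta:
        forced.setdefault(subj[m.measurement_id], []).append(m.measurement_id)
    units = [tuple(v) for v in forced.values()]
    singles = [u[0] for u in units if len(u) == 1]
    pairs_fixed = [u for u in units if len(u) == 2]
    if any(len(u) > 2 for u in units):
        raise ValueError("subjects with >2 measurements cannot form 2-measurement folds")

    def fold_ratio(fold: tuple[str, ...]) -> float:
        return float(np.mean([ratio[m] for m in fold]))

    best_plan, best_spread = None, np.inf
    for matching in _pairings(sorted(singles)):
        plan = [tuple(p) for p in matching] + list(pairs_fixed)
        spreads = [fold_ratio(f) for f in plan]
        spread = max(spreads) - min(spreads)
        if spread < best_spread:
            best_spread, best_plan = spread, plan
    if best_plan is None:
        raise ValueError("no feasible subject-exclusive pairing found")
    assignment = [sorted(f) for f in best_plan]
    assignment.sort()
    _check_partition(assignment, ids)
    return FoldPlan(scheme=scheme, assignment=assignment, seed=seed)


def _pairings(items: list[str]):
    """All perfect matchings of an even-sized list."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for i, other in enumerate(rest):
        for sub in _pairings(rest[:i] + rest[i + 1:]):
            yield [(first, other)] + sub


def _check_partition(assignment, ids) -> None:
    flat = [m for fold in assignment for m in fold]
    if sorted(flat) != sorted(ids):
        raise ValueError("fold assignment is not a partition of the measurements")


# ---------------------------------------------------------------------------
# cross-validation drivers

ModelFactory = Callable[[list[FeatureEpoch], ClassWeights, int], TrainedModel]


def benchmark_factory(spec: BenchmarkSpec) -> ModelFactory:
    def fit(train: list[FeatureEpoch], weights: ClassWeights, fold: int) -> TrainedModel:
        return train_benchmark(train, spec, weights, fold_id=fold)
    return fit


def cnn_factory(config=None) -> ModelFactory:
    def fit(train: list[FeatureEpoch], weights: ClassWeights, fold: int) -> TrainedModel:
        return train_cnn(train, config=config, weights=weights, fold_id=fold)
    return fit


def run_cross_validation(
    epochs: list[FeatureEpoch],
    plan: FoldPlan,
    factories: dict[str, ModelFactory],
) -> EvalReport:
    """Train on k-1 folds / evaluate the held-out fold for every model.

    Class weights come from training folds only. Folds whose evaluation set
    has a single class get NaN for the class-sensitive metrics and the run
    continues.
    """
    report = EvalReport(scheme=plan.scheme)
    folds = _materialize_folds(epochs, plan)
    for name, factory in factories.items():
        report.per_fold[name] = []
        report.confusions[name] = []
        for k, test_idx in enumerate(folds):
            train_idx = sorted(set(range(len(epochs))) - set(test_idx))
            train = [epochs[i] for i in train_idx]
            test = [epochs[i] for i in test_idx]
            weights = ClassWeights.from_labels([e.label for e in train])
            model = factory(train, weights, k)
            probs = model.predict_proba(test)
            y_true = np.array([1 if e.label == "QS" else 0 for e in test])
            metrics = classification_metrics(y_true, probs)
            report.per_fold[name].append(metrics)
            report.confusions[name].append(
                confusion_counts(y_true, (probs > 0.5).astype(int))
            )
    return report


def _materialize_folds(epochs: list[FeatureEpoch], plan: FoldPlan) -> list[list[int]]:
    if plan.scheme == "pooled_10fold":
        folds = [list(map(int, f)) for f in plan.assignment]
    else:
        folds = [
            [i for i, e in enumerate(epochs) if e.recording_id in fold]
            for fold in plan.assignment
        ]
    covered = sorted(i for f in folds for i in f)
    if covered != list(range(len(epochs))):
        raise ValueError("fold plan does not cover every epoch exactly once")
    return folds


def pma_sensitivity(
    epochs: list[FeatureEpoch],
    meta: Sequence[RecordingManifest],
    factory: ModelFactory,
    metric: str = "accuracy",
    n_boot: int = 10,
    seed: int = 0,
) -> dict[str, object]:
    """Leave-one-subject-out performance vs PMA, bootstrapped n_boot times.

    Training epochs are resampled with replacement per bootstrap; reports the
    Pearson r (%) and p-value per resample plus their summary. n_boot=1 with
    no resampling noise reduces to the plain estimate.
    """
    pma_by_subject: dict[str, float] = {}
    for m in meta:
        pma_by_subject.setdefault(m.subject_id, m.pma_weeks)
    plan = make_folds(meta, "leave_one_subject_out", seed=seed)
    subjects = [sorted({e.subject_id for e in epochs
                        if e.recording_id in fold})[0] for fold in plan.assignment]
    if len(subjects) < 3:
        raise ValueError("PMA sensitivity needs at least 3 subjects")
    rng = np.random.default_rng(seed)
    rs, ps = [], []
    perf_matrix = []
    for b in range(n_boot):
        perf = []
        for fold, subject in zip(plan.assignment, subjects):
            test = [e for e in epochs if e.recording_id in fold]
            train = [e for e in epochs if e.recording_id not in fold]
            if b > 0:
                idx = rng.integers(0, len(train), len(train))
                train = [train[i] for i in idx]
            if len({e.label for e in train}) < 2:
                perf.append(np.nan)
                continue
            weights = ClassWeights.from_labels([e.label for e in train])
            model = factory(train, weights, -1)
            y = np.array([1 if e.label == "QS" else 0 for e in test])
            metrics = classification_metrics(y, model.predict_proba(test))
            perf.append(metrics[metric])
        perf = np.asarray(perf, dtype=float)
        perf_matrix.append(perf)
        pma = np.array([pma_by_subject[s] for s in subjects])
        ok = np.isfinite(perf)
        if np.std(perf[ok]) == 0 or np.std(pma[ok]) == 0:
            rs.append(np.nan)
            ps.append(np.nan)
        else:
            r, p = stats.pearsonr(pma[ok], perf[ok])
            rs.append(100.0 * r)
            ps.append(p)
    rs_arr = np.asarray(rs)
    return {
        "metric": metric,
        "subjects": subjects,
        "pma": [pma_by_subject[s] for s in subjects],
        "per_boot_r": rs,
        "per_boot_p": ps,
        "r_mean": float(np.nanmean(rs_arr)),
        "r_sd": float(np.nanstd(rs_arr, ddof=1)) if n_boot > 1 else 0.0,
        "performance": [list(map(float, row)) for row in perf_matrix],
    }
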