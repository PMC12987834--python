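"""Patient-wise repeated cross-validation and the metric panel.

Protocol: patients (not segments) are split into k stratified folds, where a
patient's stratum is "has at least one culprit segment".  The complete k-fold
cross-validation is repeated several times, re-randomising the order in which
training samples are presented (folds stay fixed by default; ``refold``
re-draws them per repeat).  Each fold x repeat evaluation yields validation
scores; the operating threshold is chosen per evaluation to maximise F1, and
the panel (F1, PPV, sensitivity, specificity, accuracy, AUC) is reported as
mean +/- sample SD over all fold x repeat evaluations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix, roc_auc_score, roc_curve

from .models import ModelConfig
from .synthgen import SegmentArrays
from .training import TrainConfig, predict, train

__all__ = [
    "FoldPlan",
    "EvalResult",
    "MetricsReport",
    "stratified_patient_folds",
    "patients_from_dataset",
    "repeated_cv",
    "confusion_metrics",
    "auc",
    "roc_points",
    "f1_max_threshold",
    "naive_expected_metrics",
    "aggregate_report",
    "evaluate_results",
]

METRIC_NAMES = ("f1", "ppv", "sensitivity", "specificity", "auc", "accuracy")
METRIC_LABELS = {"f1": "F1", "ppv": "PPV", "sensitivity": "Sensitivity",
                 "specificity": "Specificity", "auc": "AUC", "accuracy": "Accuracy"}


@dataclass(frozen=True)
class FoldPlan:
    """Assignment of every patient to exactly one of k folds."""

    k: int
    assignment: dict[str, int]
    seed: int

    def fold_patients(self, f: int) -> list[str]:
        return [p for p, g in self.assignment.items() if g == f]


def patients_from_dataset(dataset: SegmentArrays) -> list[tuple[str, bool]]:
    """Patient list with the has-culprit-segment flag used for stratification."""
    out = []
    for pid in dict.fromkeys(dataset.patient_ids):  # preserve first-seen order
        mask = dataset.patient_ids == pid
        out.append((str(pid), bool(dataset.labels[mask].any())))
    return out


def stratified_patient_folds(patients: list[tuple[str, bool]], k: int,
                             seed: int) -> FoldPlan:
    """Split patients into k folds, stratified by the has-culprit flag.

    Patients are shuffled within each stratum and dealt greedily to the
    currently smallest fold, so fold sizes differ by at most one and each
    stratum's count per fold differs by at most one (exact stratification).
    Deterministic given ``seed``.
    """
    if len(patients) < k:
        raise ValueError(f"need at least k={k} patients, got {len(patients)}")
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    assignment: dict[str, int] = {}
    sizes = np.zeros(k, dtype=int)
    for flag in (True, False):
        stratum = [pid for pid, f in patients if bool(f) == flag]
        for pid in rng.permutation(stratum):
            f = int(np.argmin(sizes))  # smallest fold, lowest index on ties
            assignment[str(pid)] = f
            sizes[f] += 1
    return FoldPlan(k=k, assignment=assignment, seed=seed)


@dataclass
class EvalResult:
    """Validation scores of one fold x repeat evaluation."""

    repeat: int
    fold: int
    scores: np.ndarray
    labels: np.ndarray
    patient_ids: np.ndarray
    segment_ids: np.ndarray


def _naive_scores(train_labels: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Random labels at the training prevalence (the naive comparator)."""
    p = float(np.mean(train_labels))
    return (rng.random(n) < p).astype(float)


def repeated_cv(dataset: SegmentArrays, arch: str, model_config: ModelConfig | None,
                train_config: TrainConfig | None, k: int = 5, repeats: int = 5,
                seed: int = 0, refold: bool = False, log=None) -> list[EvalResult]:
    """Run the full repeated patient-wise CV; returns k x repeats evaluations.

    Folds are fixed across repeats by default; repeats differ in the sample
    order seen by the optimiser (``shuffle_seed`` varies with the repeat).
    No validation segment's patient ever appears in the matching train set.
    """
    patients = patients_from_dataset(dataset)
    plan = stratified_patient_folds(patients, k, seed)
    results: list[EvalResult] = []
    for r in range(repeats):
        if refold and r > 0:
            plan = stratified_patient_folds(patients, k, seed + 7919 * (r + 1))
        for f in range(k):
            val_pat = set(plan.fold_patients(f))
            val_idx = np.flatnonzero(np.isin(dataset.patient_ids, list(val_pat)))
            tr_idx = np.flatnonzero(~np.isin(dataset.patient_ids, list(val_pat)))
            tr, val = dataset.subset(tr_idx), dataset.subset(val_idx)
            if arch == "naive":
                rng = np.random.default_rng(seed * 1000 + r * 10 + f)
                scores = _naive_scores(tr.labels, len(val), rng)
            else:
                mc = ModelConfig.from_dict({**model_config.to_dict(),
                                            "init_seed": seed * 1000 + 500 + f})
                tc = TrainConfig(**{**train_config.to_dict(),
                                    "shuffle_seed": seed * 1000 + r * 10 + f})
                if log is not None:
                    log(f"repeat={r + 1} fold={f + 1} n_train={len(tr)} n_val={len(val)}")
                model, _ = train(arch, tr, mc, tc)
                scores = predict(model, val)
            results.append(EvalResult(repeat=r, fold=f, scores=np.asarray(scores, float),
                                      labels=val.labels.copy(),
                                      patient_ids=val.patient_ids.copy(),
                                      segment_ids=val.segment_ids.copy()))
    return results


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def confusion_metrics(predictions, labels) -> dict[str, float]:
    """F1 / PPV / sensitivity / specificity / accuracy from binary predictions.

    Empty-denominator conventions: PPV = 0 with no positive predictions,
    sensitivity = 0 with no positives in the labels, F1 = 0 when PPV and
    sensitivity are both 0.
    """
    predictions = np.asarray(predictions, dtype=int)
    labels = np.asarray(labels, dtype=int)
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels must have equal length")
    tn, fp, fn, tp = confusion_matrix(labels, predictions, labels=[0, 1]).ravel()
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 1.0
    ppv = tp / (tp + fp) if tp + fp else 0.0
    acc = (tp + tn) / len(labels)
    f1 = 2 * ppv * sens / (ppv + sens) if ppv + sens else 0.0
    return {"f1": f1, "ppv": ppv, "sensitivity": sens, "specificity": spec, "accuracy": acc}


def _check_two_classes(labels: np.ndarray) -> None:
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")


def auc(scores, labels) -> float:
    """Area under the ROC curve = the Mann-Whitney statistic (ties count 0.5)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    _check_two_classes(labels)
    return float(roc_auc_score(labels, scores))


def roc_points(scores, labels) -> np.ndarray:
    """ROC staircase as ordered (1 - specificity, sensitivity) pairs,
    from (0, 0) to (1, 1); its trapezoidal area equals :func:`auc`."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    _check_two_classes(labels)
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    return np.column_stack([fpr, tpr])


def f1_max_threshold(scores, labels) -> tuple[float, float]:
    """The threshold (predict positive iff score >= t) that maximises F1.

    Candidates are midpoints between consecutive sorted unique scores plus
    -inf / +inf sentinels; ties are broken toward the higher threshold (the
    more specific operating point).
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    _check_two_classes(labels)
    uniq = np.unique(scores)
    candidates = np.concatenate([[-np.inf], (uniq[:-1] + uniq[1:]) / 2.0, [np.inf]])
    best_t, best_f1 = np.inf, -1.0
    for t in candidates:  # ascending; >= keeps the highest tied threshold
        f1 = confusion_metrics(scores >= t, labels)["f1"]
        if f1 >= best_f1:
            best_t, best_f1 = float(t), f1
    return best_t, best_f1


def naive_expected_metrics(p: float) -> dict[str, float]:
    """Closed-form panel for a predictor that flips a coin at the prevalence.

    Predicting positive with probability p, independent of truth, on data
    with prevalence p gives E[sensitivity] = E[PPV] = F1 = p,
    E[specificity] = 1 - p and E[accuracy] = p^2 + (1 - p)^2.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("prevalence must lie in [0, 1]")
    return {"f1": p, "ppv": p, "sensitivity": p, "specificity": 1.0 - p,
            "accuracy": p * p + (1.0 - p) ** 2}


@dataclass
class MetricsReport:
    """Mean +/- sample SD of each metric over fold x repeat evaluations."""

    metrics: dict[str, tuple[float, float]]
    thresholds: list[float] = field(default_factory=list)
    n_evals: int = 0

    def to_dict(self) -> dict:
        return {"n_evals": self.n_evals,
                "metrics": {k: {"mean": m, "sd": s} for k, (m, s) in self.metrics.items()},
                "thresholds": list(self.thresholds)}

    @staticmethod
    def from_dict(d: dict) -> "MetricsReport":
        return MetricsReport(
            metrics={k: (v["mean"], v["sd"]) for k, v in d["metrics"].items()},
            thresholds=list(d.get("thresholds", [])), n_evals=int(d["n_evals"]))


def aggregate_report(per_eval_metrics: list[dict[str, float]],
                     thresholds: list[float] | None = None) -> MetricsReport:
    """Aggregate per-evaluation metric dicts into mean +/- sample SD."""
    if len(per_eval_metrics) < 2:
        raise ValueError("need at least two evaluations to aggregate")
    keys = per_eval_metrics[0].keys()
    metrics = {}
    for k in keys:
        vals = np.array([m[k] for m in per_eval_metrics if m[k] is not None], float)
        metrics[k] = (float(vals.mean()), float(vals.std(ddof=1)))
    return MetricsReport(metrics=metrics, thresholds=list(thresholds or []),
                         n_evals=len(per_eval_metrics))


def evaluate_results(results: list[EvalResult], threshold: str | float = "f1max",
                     with_auc: bool = True) -> tuple[MetricsReport, list[dict[str, float]]]:
    """Score every fold x repeat evaluation and aggregate the panel.

    ``threshold``: ``"f1max"`` chooses the F1-maximising threshold per
    evaluation on that evaluation's own validation scores (no pooling); a
    float applies one fixed operating point everywhere.
    """
    per_eval, thresholds = [], []
    for res in results:
        if threshold == "f1max":
            t, _ = f1_max_threshold(res.scores, res.labels)
        else:
            t = float(threshold)
        row = confusion_metrics(res.scores >= t, res.labels)
        if with_auc:
            row["auc"] = auc(res.scores, res.labels)
        per_eval.append(row)
        thresholds.append(t)
    return aggregate_report(per_eval, thresholds), per_eval
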