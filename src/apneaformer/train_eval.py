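"""Patient-level splitting, class-weighted training, and second- plus
event-level evaluation.

All splits operate on subject identifiers, never on windows, so every
window of a subject follows its subject — the grouped-cross-validation
discipline that prevents leakage between training and evaluation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

from .config import TrainConfig
from .synthetic import EventAnnotation

__all__ = [
    "SplitPlan",
    "ConfusionCounts",
    "MetricsReport",
    "split_patients",
    "make_folds",
    "class_weights",
    "train",
    "confusion",
    "compute_metrics",
    "aggregate_events",
    "match_events",
    "evaluate_predictions",
]


@dataclass
class SplitPlan:
    """Subject-level 80/20 development/test split plus k validation folds
    within the development set (each dev subject in exactly one fold)."""

    dev_subjects: list[str]
    test_subjects: list[str]
    folds: list[list[str]] = field(default_factory=list)

    def fold_split(self, k: int) -> tuple[list[str], list[str]]:
        """(train_subjects, validation_subjects) of fold k."""
        val = self.folds[k]
        train = [s for s in self.dev_subjects if s not in val]
        return train, val


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricsReport:
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    auc: float
    counts: ConfusionCounts
    event_level: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "f1": self.f1,
            "auc": self.auc,
            "confusion": {"tp": self.counts.tp, "fp": self.counts.fp,
                          "fn": self.counts.fn, "tn": self.counts.tn},
            "event_level": dict(self.event_level),
        }


def split_patients(subject_ids: list[str], test_fraction: float = 0.2,
                   seed: int = 0) -> SplitPlan:
    """Seeded random subject-level partition into development and held-out
    test sets (default 80/20)."""
    subjects = list(subject_ids)
    if len(subjects) < 5:
        raise ValueError("need at least 5 subjects for a patient-level split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(subjects))
    n_test = int(round(test_fraction * len(subjects)))
    n_test = max(n_test, 1)
    test = sorted(subjects[i] for i in order[:n_test])
    dev = sorted(subjects[i] for i in order[n_test:])
    return SplitPlan(dev_subjects=dev, test_subjects=test)


def make_folds(dev_subjects: list[str], k: int = 5, seed: int = 0,
               mode: str = "nested") -> list[list[str]]:
    """Validation-fold subject assignments.

    ``nested`` (default): a seeded partition of the dev subjects into k
    near-equal disjoint validation folds — no subject validates twice.
    ``paper_literal``: k independent seeded 23-train/7-validation splits of
    the full subject list (requires >= 8 subjects); validation sets may
    recur across folds, mirroring published 23/7 arithmetic over 30
    subjects, which cannot be a disjoint 5-fold partition.
    """
    subjects = list(dev_subjects)
    if k <= 1:
        raise ValueError("k must be at least 2")
    rng = np.random.default_rng(seed)
    if mode == "paper_literal":
        n_val = 7 if len(subjects) >= 30 else max(len(subjects) // 4, 1)
        folds = []
        for _ in range(k):
            order = rng.permutation(len(subjects))
            folds.append(sorted(subjects[i] for i in order[:n_val]))
        return folds
    if mode != "nested":
        raise ValueError("mode must be 'nested' or 'paper_literal'")
    if k > len(subjects):
        raise ValueError(f"k={k} exceeds {len(subjects)} subjects")
    order = rng.permutation(len(subjects))
    parts = np.array_split(order, k)
    return [sorted(subjects[i] for i in part) for part in parts]


def class_weights(labels: np.ndarray) -> dict[str, float]:
    """Balanced binary class weights w_c = N / (2 * N_c), which equalize
    the total weighted mass of the two classes."""
    y = np.asarray(labels).ravel()
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to derive class weights")
    n = n_pos + n_neg
    return {"weight_pos": n / (2.0 * n_pos), "weight_neg": n / (2.0 * n_neg)}


def train(classifier, X: np.ndarray, y: np.ndarray,
          config: TrainConfig | None = None):
    """Fit ``classifier`` on a windowed dataset under a TrainConfig.

    Thin wrapper over the estimator's own ``fit``; returns the fitted
    classifier (its ``history_`` holds per-epoch loss and learning rate).
    ``epochs=0`` returns the classifier untrained (initialized only).
    """
    if config is not None:
        config.validate()
        classifier.set_params(
            batch_size=config.batch_size,
            learning_rate=config.init_lr,
            weight_decay=config.weight_decay,
            lr_constant_epochs=config.lr_constant_epochs,
            lr_decay=config.lr_decay,
            lr_floor=config.lr_floor,
            epochs=config.epochs,
            class_weight=None if config.class_weighting == "none" else "balanced",
            random_state=config.seed,
        )
    return classifier.fit(X, y)


def confusion(pred_seconds: np.ndarray, true_seconds: np.ndarray) -> ConfusionCounts:
    """Second-level 2x2 contingency counts."""
    p = np.asarray(pred_seconds).ravel().astype(bool)
    t = np.asarray(true_seconds).ravel().astype(bool)
    if p.shape != t.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {t.shape}")
    return ConfusionCounts(
        tp=int(np.sum(p & t)),
        fp=int(np.sum(p & ~t)),
        fn=int(np.sum(~p & t)),
        tn=int(np.sum(~p & ~t)),
    )


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN",
                      RuntimeWarning, stacklevel=3)
        return float("nan")
    return num / den


def compute_metrics(counts: ConfusionCounts,
                    probabilities: np.ndarray | None = None,
                    truths: np.ndarray | None = None,
                    event_level: dict[str, int] | None = None) -> MetricsReport:
    """Standard ratio metrics from the confusion counts, plus ROC-AUC
    (trapezoidal, micro-averaged over all pooled seconds) when
    probabilities and truths are supplied."""
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    accuracy = _ratio(tp + tn, counts.n, "accuracy")
    sensitivity = _ratio(tp, tp + fn, "sensitivity")
    precision = _ratio(tp, tp + fp, "precision")
    specificity = _ratio(tn, tn + fp, "specificity")
    if np.isnan(precision) or np.isnan(sensitivity) or precision + sensitivity == 0:
        warnings.warn("F1 undefined; reporting NaN", RuntimeWarning, stacklevel=2)
        f1 = float("nan")
    else:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)
    auc = float("nan")
    if probabilities is not None and truths is not None:
        t = np.asarray(truths).ravel()
        pr = np.asarray(probabilities).ravel()
        if t.min() != t.max():
            auc = float(roc_auc_score(t, pr))
        else:
            warnings.warn("AUC undefined with a single class; reporting NaN",
                          RuntimeWarning, stacklevel=2)
    return MetricsReport(accuracy=accuracy, sensitivity=sensitivity,
                         specificity=specificity, precision=precision,
                         f1=f1, auc=auc, counts=counts,
                         event_level=event_level or {})


def aggregate_events(per_second_mask: np.ndarray,
                     min_duration: float = 0.0) -> list[tuple[float, float]]:
    """Collapse maximal runs of consecutive positive seconds into detected
    events [run_start, run_end+1). Optional minimum-duration filter."""
    m = np.asarray(per_second_mask).astype(bool).astype(int)
    if m.size == 0:
        return []
    edges = np.diff(np.concatenate(([0], m, [0])))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    return [(float(s), float(e)) for s, e in zip(starts, ends)
            if e - s >= min_duration]


def match_events(detected: list, annotated: list,
                 min_overlap: float = 0.0) -> dict[str, int]:
    """Event-level counts by any-overlap matching.

    Each annotated event is matched by at most one detected event, greedily
    in start order. ``min_overlap`` optionally requires the overlap to
    cover at least that fraction of the annotated event.
    Returns matched / missed / spurious counts.
    """
    def bounds(ev):
        if isinstance(ev, EventAnnotation):
            return ev.start, ev.end
        return float(ev[0]), float(ev[1])

    det = sorted(bounds(e) for e in detected)
    ann = sorted(bounds(e) for e in annotated)
    used = [False] * len(det)
    matched = 0
    for a_start, a_end in ann:
        for i, (d_start, d_end) in enumerate(det):
            if used[i]:
                continue
            overlap = min(a_end, d_end) - max(a_start, d_start)
            if overlap > 0 and overlap >= min_overlap * (a_end - a_start):
                used[i] = True
                matched += 1
                break
    return {
        "matched": matched,
        "missed": len(ann) - matched,
        "spurious": len(det) - matched,
    }


def evaluate_predictions(pred: np.ndarray, proba: np.ndarray,
                         truth: np.ndarray) -> MetricsReport:
    """Full second- and event-level report for flattened or windowed
    per-second arrays (windows are concatenated in order for the
    event-level comparison)."""
    counts = confusion(pred, truth)
    detected = aggregate_events(np.asarray(pred).ravel())
    annotated = aggregate_events(np.asarray(truth).ravel())
    ev = match_events(detected, annotated)
    return compute_metrics(counts, proba, truth, event_level=ev)
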