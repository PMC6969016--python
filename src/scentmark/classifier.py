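"""Native k-nearest-neighbour posture classification and evaluation.

Training sets are built as a uniform random sample of raw triaxial records
per class (default 50 per scent class, 500 "other"); testing sets take every
remaining scent record plus a random 3000 "other" records, so performance is
not driven by the overwhelming prevalence of non-marking behaviour.  The
classifier votes among the k Euclidean-nearest training records, with k tuned
by stratified cross-validated grid search preferring small odd k.

Metrics are the standard multiclass one-vs-rest set: accuracy, precision
TP/(TP+FP), recall TP/(TP+FN), F1 = 2*precision*recall/(precision+recall),
and rank-statistic AUC from vote-fraction scores, each aggregated by a
prevalence-weighted average.

Deterministic tie rules (the conventional choices, stated explicitly):

* distance ties at the k-th neighbour keep the lowest training index;
* a deadlocked majority vote falls to the tied class holding the nearest
  neighbour (nearer points carry more information);
* in distance-weighted voting an exact match (distance 0) wins outright;
* undefined precision/recall (empty denominator) is reported as 0 with a
  warning.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import rankdata

from .classes import BehaviourClass, SCENT_CLASSES
from .io import AccelTrace, LabelTrack

DEFAULT_K_GRID = (1, 3, 5, 7, 9, 11, 13, 15, 17, 19, 21)


# ---------------------------------------------------------------------------
# Training / testing set construction
# ---------------------------------------------------------------------------


@dataclass
class TrainingSet:
    """Labelled raw triaxial records sampled from a trace."""

    records: np.ndarray  # (n, 3) float, units of g
    labels: np.ndarray  # (n,) object of BehaviourClass
    indices: np.ndarray  # (n,) int sample indices into the source trace
    source_id: str = ""

    def __post_init__(self) -> None:
        self.records = np.asarray(self.records, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        self.indices = np.asarray(self.indices, dtype=int)
        if len(set(self.indices.tolist())) != len(self.indices):
            raise ValueError("duplicate record indices in training set")

    def __len__(self) -> int:
        return len(self.labels)

    def class_counts(self) -> dict[BehaviourClass, int]:
        out: dict[BehaviourClass, int] = {}
        for c in self.labels:
            out[c] = out.get(c, 0) + 1
        return out

    def classes(self) -> list[BehaviourClass]:
        return sorted(set(self.labels.tolist()), key=lambda c: c.value)


def _per_class_indices(
    trace: AccelTrace, labels: LabelTrack
) -> dict[BehaviourClass, np.ndarray]:
    y = labels.sample_classes(trace.t)
    out: dict[BehaviourClass, np.ndarray] = {}
    for cls in sorted(set(y.tolist()), key=lambda c: c.value):
        out[cls] = np.nonzero(y == cls)[0]
    return out


def build_training_set(
    trace: AccelTrace,
    labels: LabelTrack,
    n_scent: int = 50,
    n_other: int = 500,
    seed: int | None = 0,
    source_id: str = "",
) -> TrainingSet:
    """Uniform random sample without replacement: ``n_scent`` records per
    scent class present plus ``n_other`` "other" records."""
    rng = np.random.default_rng(seed)
    pools = _per_class_indices(trace, labels)
    chosen: list[np.ndarray] = []
    for cls in sorted(pools, key=lambda c: c.value):
        want = n_other if cls == BehaviourClass.OTHER else n_scent
        pool = pools[cls]
        if len(pool) < want:
            raise ValueError(
                f"class {cls.value}: only {len(pool)} samples available, "
                f"{want} requested"
            )
        chosen.append(rng.choice(pool, size=want, replace=False))
    idx = np.sort(np.concatenate(chosen))
    y = labels.sample_classes(trace.t[idx])
    return TrainingSet(
        records=trace.xyz()[idx], labels=y, indices=idx, source_id=source_id
    )


def build_testing_set(
    trace: AccelTrace,
    labels: LabelTrack,
    training: TrainingSet,
    n_other_test: int = 3000,
    seed: int | None = 0,
) -> TrainingSet:
    """All scent records not used in training plus ``n_other_test`` random
    "other" records (capped at availability), disjoint from training."""
    rng = np.random.default_rng(seed)
    pools = _per_class_indices(trace, labels)
    train_idx = set(training.indices.tolist())
    chosen: list[np.ndarray] = []
    for cls in sorted(pools, key=lambda c: c.value):
        pool = np.array(
            [i for i in pools[cls] if i not in train_idx], dtype=int
        )
        if cls == BehaviourClass.OTHER:
            if len(pool) < n_other_test:
                warnings.warn(
                    f"only {len(pool)} 'other' records available for testing "
                    f"(requested {n_other_test}); using all",
                    stacklevel=2,
                )
                take = pool
            else:
                take = rng.choice(pool, size=n_other_test, replace=False)
        else:
            take = pool
        chosen.append(take)
    idx = np.sort(np.concatenate(chosen))
    y = labels.sample_classes(trace.t[idx])
    return TrainingSet(
        records=trace.xyz()[idx],
        labels=y,
        indices=idx,
        source_id=training.source_id,
    )


# ---------------------------------------------------------------------------
# KNN
# ---------------------------------------------------------------------------


@dataclass
class KnnClassifier:
    """K-nearest-neighbour voter over raw triaxial records."""

    training: TrainingSet
    k: int = 3
    vote: str = "majority"  # or "distance_weighted"

    def __post_init__(self) -> None:
        if self.k < 1 or self.k % 2 == 0:
            raise ValueError(f"k must be odd and positive, got {self.k}")
        if self.k > len(self.training):
            raise ValueError(
                f"k={self.k} exceeds training size {len(self.training)}"
            )
        if self.vote not in ("majority", "distance_weighted"):
            raise ValueError(f"unknown vote scheme {self.vote!r}")

    def predict(self, queries: np.ndarray) -> np.ndarray:
        return knn_predict(self, queries)

    def predict_scores(
        self, queries: np.ndarray
    ) -> tuple[np.ndarray, dict[BehaviourClass, np.ndarray]]:
        return knn_predict(self, queries, return_scores=True)

    # JSON (de)serialisation -------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        doc = {
            "k": self.k,
            "vote": self.vote,
            "source_id": self.training.source_id,
            "records": self.training.records.tolist(),
            "labels": [c.value for c in self.training.labels],
            "indices": self.training.indices.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "KnnClassifier":
        with open(path) as fh:
            doc = json.load(fh)
        ts = TrainingSet(
            records=np.array(doc["records"], dtype=float),
            labels=np.array(
                [BehaviourClass(v) for v in doc["labels"]], dtype=object
            ),
            indices=np.array(doc["indices"], dtype=int),
            source_id=doc.get("source_id", ""),
        )
        return cls(training=ts, k=doc["k"], vote=doc["vote"])


def _vote(
    neigh_labels: list[BehaviourClass],
    neigh_dists: np.ndarray,
    vote: str,
    classes: list[BehaviourClass],
) -> tuple[BehaviourClass, dict[BehaviourClass, float]]:
    """One query's vote; returns (winner, per-class vote fractions)."""
    if vote == "distance_weighted":
        zero = [c for c, d in zip(neigh_labels, neigh_dists) if d == 0.0]
        if zero:
            scores = {c: 0.0 for c in classes}
            # exact match wins outright; score mass on zero-distance labels
            counts: dict[BehaviourClass, int] = {}
            for c in zero:
                counts[c] = counts.get(c, 0) + 1
            for c, n in counts.items():
                scores[c] = n / len(zero)
            best = max(counts.values())
            winner = min(
                (c for c, n in counts.items() if n == best),
                key=lambda c: c.value,
            )
            return winner, scores
        weights = {c: 0.0 for c in classes}
        for c, d in zip(neigh_labels, neigh_dists):
            weights[c] += 1.0 / d
        total = sum(weights.values())
        scores = {c: w / total for c, w in weights.items()}
        best = max(weights.values())
        tied = [c for c in classes if weights[c] == best]
    else:
        counts = {c: 0 for c in classes}
        for c in neigh_labels:
            counts[c] += 1
        scores = {c: counts[c] / len(neigh_labels) for c in classes}
        best = max(counts.values())
        tied = [c for c in classes if counts[c] == best]
    if len(tied) == 1:
        return tied[0], scores
    # deadlock: tied class with the nearest representative wins
    for c in neigh_labels:  # neighbours are distance-ordered
        if c in tied:
            return c, scores
    return tied[0], scores  # unreachable


def knn_predict(
    model: KnnClassifier,
    queries: np.ndarray,
    return_scores: bool = False,
    chunk: int = 8192,
):
    """Classify each query by a vote of its k nearest training records.

    Distances are Euclidean in g.  With ``return_scores=True`` also returns
    per-class vote fractions (the AUC scores).
    """
    queries = np.atleast_2d(np.asarray(queries, dtype=float))
    if queries.size == 0:
        empty = np.array([], dtype=object)
        if return_scores:
            return empty, {c: np.array([]) for c in model.training.classes()}
        return empty
    train = model.training.records
    labels = model.training.labels
    classes = model.training.classes()
    k = model.k
    preds = np.empty(len(queries), dtype=object)
    scores = {c: np.empty(len(queries)) for c in classes}
    for lo in range(0, len(queries), chunk):
        q = queries[lo : lo + chunk]
        d = np.sqrt(((q[:, None, :] - train[None, :, :]) ** 2).sum(axis=2))
        # stable sort: equal distances resolve to the lowest training index
        order = np.argsort(d, axis=1, kind="stable")[:, :k]
        for i in range(len(q)):
            nn = order[i]
            winner, sc = _vote(
                [labels[j] for j in nn], d[i, nn], model.vote, classes
            )
            preds[lo + i] = winner
            for c in classes:
                scores[c][lo + i] = sc[c]
    if return_scores:
        return preds, scores
    return preds


# ---------------------------------------------------------------------------
# k tuning
# ---------------------------------------------------------------------------


def _stratified_folds(
    labels: np.ndarray, folds: int, rng: np.random.Generator
) -> np.ndarray:
    """Fold id per record; each class dealt round-robin after a shuffle."""
    fold_of = np.empty(len(labels), dtype=int)
    for cls in sorted(set(labels.tolist()), key=lambda c: c.value):
        idx = np.nonzero(labels == cls)[0]
        if len(idx) < folds:
            raise ValueError(
                f"class {cls.value} has {len(idx)} records, fewer than "
                f"{folds} folds"
            )
        idx = rng.permutation(idx)
        for pos, i in enumerate(idx):
            fold_of[i] = pos % folds
    return fold_of


def tune_k(
    trace: AccelTrace,
    labels: LabelTrack,
    k_grid: tuple[int, ...] = DEFAULT_K_GRID,
    folds: int = 5,
    seed: int | None = 0,
    n_scent: int = 50,
    n_other: int = 500,
    vote: str = "majority",
    training: TrainingSet | None = None,
) -> tuple[int, list[dict]]:
    """Grid-search k by stratified cross-validated accuracy.

    Ties are broken toward the smallest k.  Returns ``(k_best, cv_table)``
    where the table holds per-k mean and per-fold accuracies.
    """
    if training is None:
        training = build_training_set(
            trace, labels, n_scent=n_scent, n_other=n_other, seed=seed
        )
    rng = np.random.default_rng(seed)
    fold_of = _stratified_folds(training.labels, folds, rng)
    cv_table: list[dict] = []
    best_k, best_acc = None, -1.0
    for k in sorted(k_grid):
        fold_accs = []
        for f in range(folds):
            tr = fold_of != f
            te = ~tr
            sub = TrainingSet(
                records=training.records[tr],
                labels=training.labels[tr],
                indices=training.indices[tr],
            )
            model = KnnClassifier(training=sub, k=min(k, len(sub)), vote=vote)
            pred = model.predict(training.records[te])
            fold_accs.append(float(np.mean(pred == training.labels[te])))
        mean_acc = float(np.mean(fold_accs))
        cv_table.append({"k": k, "mean_accuracy": mean_acc, "folds": fold_accs})
        if mean_acc > best_acc:  # strict: ties keep the smaller k
            best_k, best_acc = k, mean_acc
    return int(best_k), cv_table


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


@dataclass
class ClassMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    precision: float
    recall: float
    f1: float
    auc: float | None = None

    @property
    def support(self) -> int:
        return self.tp + self.fn


@dataclass
class MetricsReport:
    """Per-class one-vs-rest counts and the prevalence-weighted aggregates."""

    per_class: dict[BehaviourClass, ClassMetrics]
    accuracy: float
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float
    weighted_auc: float | None
    n_samples: int
    detections: dict[BehaviourClass, tuple[int, int]] = field(
        default_factory=dict
    )

    def to_dict(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "accuracy": self.accuracy,
            "weighted_precision": self.weighted_precision,
            "weighted_recall": self.weighted_recall,
            "weighted_f1": self.weighted_f1,
            "weighted_auc": self.weighted_auc,
            "per_class": {
                c.value: {
                    "tp": m.tp,
                    "fp": m.fp,
                    "tn": m.tn,
                    "fn": m.fn,
                    "precision": m.precision,
                    "recall": m.recall,
                    "f1": m.f1,
                    "auc": m.auc,
                }
                for c, m in self.per_class.items()
            },
            "detections": {
                c.value: f"{hit}/{tot}"
                for c, (hit, tot) in self.detections.items()
            },
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)


def _auc_rank(y_pos: np.ndarray, score: np.ndarray) -> float | None:
    """One-vs-rest AUC via the Mann-Whitney rank statistic (midranks)."""
    n_pos = int(y_pos.sum())
    n_neg = len(y_pos) - n_pos
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = rankdata(score)
    return float(
        (ranks[y_pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    )


def evaluate(
    y_true,
    y_pred,
    scores: dict[BehaviourClass, np.ndarray] | None = None,
    classes: list[BehaviourClass] | None = None,
) -> MetricsReport:
    """Multiclass one-vs-rest metrics with prevalence-weighted aggregates.

    ``scores`` maps each class to a per-sample score (vote fractions) and
    enables AUC.  Classes with an empty precision/recall denominator score 0
    with a warning and still enter the weighted averages by prevalence.
    """
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred lengths differ")
    n = len(y_true)
    if n == 0:
        raise ValueError("cannot evaluate empty label vectors")
    if classes is None:
        classes = sorted(
            set(y_true.tolist()) | set(y_pred.tolist()), key=lambda c: c.value
        )
    per_class: dict[BehaviourClass, ClassMetrics] = {}
    accuracy = float(np.mean(y_true == y_pred))
    w_prec = w_rec = w_f1 = 0.0
    w_auc, auc_weight = 0.0, 0.0
    for c in classes:
        pos_true = y_true == c
        pos_pred = y_pred == c
        tp = int(np.sum(pos_true & pos_pred))
        fp = int(np.sum(~pos_true & pos_pred))
        fn = int(np.sum(pos_true & ~pos_pred))
        tn = n - tp - fp - fn
        if tp + fp == 0:
            warnings.warn(
                f"precision undefined for class {c.value} (no positive "
                "predictions); reporting 0",
                stacklevel=2,
            )
            prec = 0.0
        else:
            prec = tp / (tp + fp)
        if tp + fn == 0:
            warnings.warn(
                f"recall undefined for class {c.value} (no true samples); "
                "reporting 0",
                stacklevel=2,
            )
            rec = 0.0
        else:
            rec = tp / (tp + fn)
        f1 = 0.0 if prec + rec == 0 else 2 * prec * rec / (prec + rec)
        auc = None
        if scores is not None and c in scores:
            auc = _auc_rank(pos_true, np.asarray(scores[c], dtype=float))
        per_class[c] = ClassMetrics(tp, fp, tn, fn, prec, rec, f1, auc)
        prevalence = (tp + fn) / n
        w_prec += prevalence * prec
        w_rec += prevalence * rec
        w_f1 += prevalence * f1
        if auc is not None:
            w_auc += prevalence * auc
            auc_weight += prevalence
    weighted_auc = w_auc / auc_weight if auc_weight > 0 else None
    report = MetricsReport(
        per_class=per_class,
        accuracy=accuracy,
        weighted_precision=w_prec,
        weighted_recall=w_rec,
        weighted_f1=w_f1,
        weighted_auc=weighted_auc,
        n_samples=n,
    )
    # algebraic identity: prevalence-weighted recall == accuracy
    assert abs(report.weighted_recall - report.accuracy) < 1e-9
    return report


# ---------------------------------------------------------------------------
# Cross-individual transfer
# ---------------------------------------------------------------------------


def cross_individual_matrix(
    datasets: list[tuple[AccelTrace, LabelTrack]],
    n_scent: int = 50,
    n_other: int = 500,
    n_other_test: int = 3000,
    k_grid: tuple[int, ...] = DEFAULT_K_GRID,
    folds: int = 5,
    seed: int | None = 0,
    vote: str = "majority",
) -> list[list[MetricsReport]]:
    """Train on individual i, evaluate on individual j's testing set, for
    every ordered pair (surrogate-transfer experiment).

    The diagonal is ordinary self-evaluation.  All datasets must share the
    same class vocabulary.
    """
    if len(datasets) < 2:
        raise ValueError("need at least 2 datasets")
    vocabs = [
        frozenset(
            c for _s, _e, c in labels.intervals
        )
        for _tr, labels in datasets
    ]
    ref = vocabs[0]
    for i, v in enumerate(vocabs[1:], start=1):
        if v != ref:
            diff = sorted(c.value for c in ref ^ v)
            raise ValueError(
                f"dataset 0 and dataset {i} differ in classes: {diff}"
            )
    models, test_sets = [], []
    for i, (trace, labels) in enumerate(datasets):
        training = build_training_set(
            trace, labels, n_scent=n_scent, n_other=n_other,
            seed=seed, source_id=f"individual_{i}",
        )
        k_best, _ = tune_k(
            trace, labels, k_grid=k_grid, folds=folds, seed=seed,
            training=training, vote=vote,
        )
        models.append(KnnClassifier(training=training, k=k_best, vote=vote))
        test_sets.append(
            build_testing_set(
                trace, labels, training, n_other_test=n_other_test, seed=seed
            )
        )
    matrix: list[list[MetricsReport]] = []
    for model in models:
        row = []
        for test in test_sets:
            pred, scores = model.predict_scores(test.records)
            row.append(evaluate(test.labels, pred, scores=scores))
        matrix.append(row)
    return matrix
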