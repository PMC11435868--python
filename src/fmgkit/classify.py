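"""Trial-segregated classifier evaluation.

Static-gesture frames cut from the same trial are highly correlated, so
windows must never straddle the train/test boundary: entire trials are
held out.  With ``n`` recorded trials and ``r`` held out per split, every
one of the C(n, r) = n!/(r!(n-r)!) combinations is evaluated and the
scores averaged — a trial-segregated variant of k-fold cross-validation.
At the default 2:1 train:test ratio, 3 trials give 3 splits (inter-trial
protocol, one session) and 6 trials give 15 (inter-session protocol, two
pooled sessions).

Seven classical classifiers are benchmarked: Gaussian naive Bayes, NuSVC,
quadratic and linear discriminant analysis, random forest, k-nearest
neighbours and a decision tree.  Features are standardised (zero mean,
unit variance, fitted on the training folds only) inside every model's
pipeline.  Wall-clock fit+predict time is reported for interface parity
with bench tables but is hardware-dependent and carries no contract.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Hashable, Sequence

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score, confusion_matrix, log_loss
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import NuSVC
from sklearn.tree import DecisionTreeClassifier

from .features import FeaturedFrame

TrialId = Hashable


def _model_factories(seed: int):
    return {
        "GaussianNB": lambda: GaussianNB(),
        "NuSVC": lambda: NuSVC(probability=True, random_state=seed),
        # Small shrinkage: selected feature sets can contain exactly
        # collinear pairs (e.g. MAV = IAV/W), which makes the per-class
        # covariance singular under the unregularised estimator.
        "QDA": lambda: QuadraticDiscriminantAnalysis(reg_param=1e-3),
        "LDA": lambda: LinearDiscriminantAnalysis(),
        "RF": lambda: RandomForestClassifier(n_estimators=100, random_state=seed),
        "K-NN": lambda: KNeighborsClassifier(),
        "DT": lambda: DecisionTreeClassifier(random_state=seed),
    }


MODEL_NAMES: tuple[str, ...] = ("GaussianNB", "NuSVC", "QDA", "LDA", "RF", "K-NN", "DT")


@dataclass(frozen=True)
class SplitPlan:
    """All C(n, r) train/test trial partitions, lexicographically ordered."""

    trial_ids: tuple[TrialId, ...]
    r: int
    partitions: tuple[tuple[tuple[TrialId, ...], tuple[TrialId, ...]], ...]

    @property
    def n(self) -> int:
        return len(self.trial_ids)

    def __len__(self) -> int:
        return len(self.partitions)


def make_split_plan(
    trial_ids: Sequence[TrialId] | int,
    test_fraction: float = 1 / 3,
) -> SplitPlan:
    """Enumerate every train/test partition holding out r trials.

    ``trial_ids`` may be an explicit sequence of identifiers or an integer
    ``n`` (shorthand for ids ``0..n-1``).  ``r = round(test_fraction * n)``
    and must satisfy ``1 <= r < n``.  Partitions are generated in
    deterministic lexicographic order of the held-out combination.
    """
    if isinstance(trial_ids, int):
        trial_ids = tuple(range(trial_ids))
    ids = tuple(sorted(trial_ids))
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 trials")
    if len(set(ids)) != n:
        raise ValueError("trial ids must be unique")
    r = round(test_fraction * n)
    if r < 1:
        raise ValueError("test_fraction too small: no trial would be held out")
    if r >= n:
        raise ValueError("test_fraction too large: no trial left for training")
    partitions = []
    for test in combinations(ids, r):
        train = tuple(t for t in ids if t not in test)
        partitions.append((train, test))
    return SplitPlan(trial_ids=ids, r=r, partitions=tuple(partitions))


def frames_to_xy(
    frames: Sequence[FeaturedFrame],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack frames into (X, y, trial_keys) arrays for model fitting."""
    X = np.vstack([f.values for f in frames])
    y = np.asarray([f.label for f in frames])
    trials = np.fromiter((f.trial_key for f in frames), dtype=object, count=len(frames))
    return X, y, trials


@dataclass
class ModelResult:
    name: str
    accuracy_mean: float
    accuracy_sd: float
    log_loss_mean: float
    log_loss_sd: float
    time_mean_s: float
    per_partition_accuracy: list[float] = field(default_factory=list)


@dataclass
class ClassifierReport:
    results: dict[str, ModelResult]
    n_partitions: int
    labels: tuple[str, ...]

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "model": r.name,
                "accuracy_mean": r.accuracy_mean,
                "accuracy_sd": r.accuracy_sd,
                "log_loss_mean": r.log_loss_mean,
                "log_loss_sd": r.log_loss_sd,
                "time_mean_s": r.time_mean_s,
            }
            for r in self.results.values()
        ]
        return pd.DataFrame(rows)

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False)
        return path


def _partition_indices(
    trials: np.ndarray, partition: tuple[tuple, tuple]
) -> tuple[np.ndarray, np.ndarray]:
    train_ids, test_ids = partition
    train_set, test_set = set(train_ids), set(test_ids)
    in_train = np.fromiter((t in train_set for t in trials), dtype=bool, count=len(trials))
    in_test = np.fromiter((t in test_set for t in trials), dtype=bool, count=len(trials))
    if (in_train & in_test).any():
        raise AssertionError("trial segregation violated: overlapping partition")
    return np.nonzero(in_train)[0], np.nonzero(in_test)[0]


def evaluate(
    frames: Sequence[FeaturedFrame],
    plan: SplitPlan,
    models: Sequence[str] | None = None,
    seed: int = 0,
) -> ClassifierReport:
    """Fit and score every model on every partition of the plan.

    All frames of a trial stay on the same side of each split (asserted on
    every partition).  Accuracy, per-partition-averaged log loss and mean
    wall time are reported per model.  A partition whose training set
    lacks a label present in its test set raises ``ValueError`` — under a
    balanced recording protocol this cannot happen, and silently skipping
    would bias the average.
    """
    models = list(models) if models is not None else list(MODEL_NAMES)
    factories = _model_factories(seed)
    unknown = set(models) - set(factories)
    if unknown:
        raise ValueError(f"unknown model names: {sorted(unknown)}")

    X, y, trials = frames_to_xy(frames)
    labels = tuple(sorted(str(v) for v in set(y)))
    if len(labels) < 2:
        raise ValueError("need at least 2 gesture labels")
    frame_trials = set(trials.tolist())
    for tid in plan.trial_ids:
        if tid not in frame_trials:
            raise ValueError(f"plan trial {tid!r} has no frames")

    results: dict[str, ModelResult] = {}
    for name in models:
        accs, losses, times = [], [], []
        for partition in plan.partitions:
            tr, te = _partition_indices(trials, partition)
            train_labels = set(y[tr])
            missing = set(y[te]) - train_labels
            if missing:
                raise ValueError(
                    f"partition {partition} lacks training labels {sorted(missing)}"
                )
            pipe = make_pipeline(StandardScaler(), factories[name]())
            t0 = time.perf_counter()
            pipe.fit(X[tr], y[tr])
            pred = pipe.predict(X[te])
            proba = pipe.predict_proba(X[te])
            times.append(time.perf_counter() - t0)
            accs.append(accuracy_score(y[te], pred))
            losses.append(log_loss(y[te], proba, labels=list(pipe.classes_)))
        results[name] = ModelResult(
            name=name,
            accuracy_mean=float(np.mean(accs)),
            accuracy_sd=float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
            log_loss_mean=float(np.mean(losses)),
            log_loss_sd=float(np.std(losses, ddof=1)) if len(losses) > 1 else 0.0,
            time_mean_s=float(np.mean(times)),
            per_partition_accuracy=[float(a) for a in accs],
        )
    return ClassifierReport(results=results, n_partitions=len(plan), labels=labels)


def confusion(
    frames: Sequence[FeaturedFrame],
    plan: SplitPlan,
    model: str = "LDA",
    seed: int = 0,
) -> tuple[tuple[str, ...], np.ndarray]:
    """Row-normalised confusion matrix aggregated over all partitions.

    Predictions from every partition's test folds are pooled, then each
    row is normalised by its true-label count.  Returns (labels, matrix).
    """
    factories = _model_factories(seed)
    if model not in factories:
        raise ValueError(f"unknown model {model!r}")
    X, y, trials = frames_to_xy(frames)
    labels = tuple(sorted(str(v) for v in set(y)))
    y_true_all, y_pred_all = [], []
    for partition in plan.partitions:
        tr, te = _partition_indices(trials, partition)
        missing = set(y[te]) - set(y[tr])
        if missing:
            raise ValueError(
                f"partition {partition} lacks training labels {sorted(missing)}"
            )
        pipe = make_pipeline(StandardScaler(), factories[model]())
        pipe.fit(X[tr], y[tr])
        y_true_all.extend(y[te])
        y_pred_all.extend(pipe.predict(X[te]))
    matrix = confusion_matrix(
        y_true_all, y_pred_all, labels=list(labels), normalize="true"
    )
    return labels, matrix


def write_confusion(
    labels: Sequence[str], matrix: np.ndarray, path: str | Path
) -> Path:
    path = Path(path)
    pd.DataFrame(matrix, index=list(labels), columns=list(labels)).to_csv(path)
    return path


def train_final_model(
    frames: Sequence[FeaturedFrame], model: str = "LDA", seed: int = 0
):
    """Fit one model on *all* frames for online use after benchmarking."""
    factories = _model_factories(seed)
    if model not in factories:
        raise ValueError(f"unknown model {model!r}")
    X, y, _ = frames_to_xy(frames)
    pipe = make_pipeline(StandardScaler(), factories[model]())
    pipe.fit(X, y)
    return pipe
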