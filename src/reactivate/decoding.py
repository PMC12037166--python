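"""Linear SVM task-vs-replay decoder and sliding-window rest scoring.

The decoder is a soft-margin linear SVM (LIBSVM via scikit-learn) with a
fixed regularization constant C = 1, trained on labeled block samples from
the task sessions.  Rest runs are scored by applying the decision function
to every sliding window; the summary statistic is the *task fraction*: the
percentage of windows labeled task.  A window with decision value exactly
zero is labeled non-task (conservative tie rule).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

from .core import REPLAY, TASK
from .features import ORDERING_TAG, SplitPlan, loso_splits, stack_samples

__all__ = [
    "DecoderModel",
    "RestLabeling",
    "train_decoder",
    "decision_values",
    "score_rest",
    "loso_accuracy",
    "volume_level_fraction",
]


@dataclass(frozen=True)
class DecoderModel:
    """Trained linear decoder: ``decision(x) = weights @ x + bias``.

    Positive decision values mean task.  ``feature_contract`` must match
    every sample the model is asked to score.
    """

    weights: np.ndarray
    bias: float
    C: float
    training_sessions: tuple
    window_len: int
    n_voxels: int

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if not np.isfinite(w).all() or not np.isfinite(self.bias):
            raise ValueError("decoder weights/bias must be finite")
        if w.size != self.window_len * self.n_voxels:
            raise ValueError("weight length does not match feature contract")
        object.__setattr__(self, "weights", w)

    @property
    def feature_contract(self) -> tuple:
        return (self.window_len, self.n_voxels, ORDERING_TAG)


@dataclass(frozen=True)
class RestLabeling:
    """Per-window task/non-task labels for one rest run.

    ``task_fraction`` is always recomputed from the stored labels, so the
    two can never disagree.
    """

    is_task: np.ndarray  # bool per window, in window order
    session_id: str
    method: str  # "svm" or "rsa"

    def __post_init__(self) -> None:
        object.__setattr__(self, "is_task", np.asarray(self.is_task, dtype=bool))

    @property
    def n_windows(self) -> int:
        return self.is_task.size

    @property
    def task_fraction(self) -> float:
        """Percentage of windows labeled task."""
        return 100.0 * float(self.is_task.mean())

    def concat(self, other: "RestLabeling") -> "RestLabeling":
        if other.method != self.method:
            raise ValueError("cannot concatenate labelings from different methods")
        return RestLabeling(
            np.concatenate([self.is_task, other.is_task]),
            session_id=f"{self.session_id}+{other.session_id}",
            method=self.method,
        )


def train_decoder(samples, C: float = 1.0) -> DecoderModel:
    """Fit the linear SVM on labeled block samples.

    Requires both classes; deterministic given identical input order
    (LIBSVM with tolerance 1e-6).  Weights are oriented so that positive
    decision values mean task.
    """
    X, labels = stack_samples(samples)
    classes = set(labels)
    if classes != {TASK, REPLAY}:
        raise ValueError(
            f"training needs both '{TASK}' and '{REPLAY}' samples, got {sorted(classes)}"
        )
    y = np.where(labels == TASK, 1, -1)
    svc = SVC(kernel="linear", C=C, tol=1e-6, shrinking=True)
    svc.fit(X, y)
    # classes_ is sorted [-1, 1]; positive decision_function => class +1 == task
    return DecoderModel(
        weights=svc.coef_[0],
        bias=float(svc.intercept_[0]),
        C=C,
        training_sessions=tuple(dict.fromkeys(s.session_id for s in samples)),
        window_len=samples[0].window_len,
        n_voxels=samples[0].n_voxels,
    )


def _check_contract(model: DecoderModel, samples) -> np.ndarray:
    X, _ = stack_samples(samples)
    if samples[0].feature_contract != model.feature_contract:
        raise ValueError(
            f"feature contract mismatch: model {model.feature_contract} "
            f"vs samples {samples[0].feature_contract}"
        )
    return X


def decision_values(model: DecoderModel, samples) -> np.ndarray:
    """Signed distances ``w @ x + b`` for each sample (positive = task)."""
    X = _check_contract(model, samples)
    return X @ model.weights + model.bias


def score_rest(model: DecoderModel, rest_windows, session_id: str | None = None) -> RestLabeling:
    """Label each rest window task iff its decision value is strictly positive."""
    d = decision_values(model, rest_windows)
    return RestLabeling(
        is_task=d > 0.0,
        session_id=session_id or rest_windows[0].session_id,
        method="svm",
    )


def loso_accuracy(samples, C: float = 1.0, splits: SplitPlan | None = None) -> tuple:
    """Leave-one-session-out cross-validated accuracy.

    Returns ``(mean_accuracy_pct, {test_session: fold_accuracy_pct})``.
    """
    if splits is None:
        splits = loso_splits(samples)
    fold_acc = {}
    for train_ids, test_id in splits.folds:
        train = [s for s in samples if s.session_id in train_ids]
        test = [s for s in samples if s.session_id == test_id]
        model = train_decoder(train, C=C)
        d = decision_values(model, test)
        predicted = np.where(d > 0.0, TASK, REPLAY)
        actual = np.array([s.label for s in test])
        fold_acc[test_id] = 100.0 * float((predicted == actual).mean())
    mean_acc = float(np.mean(list(fold_acc.values())))
    return mean_acc, fold_acc


def volume_level_fraction(
    labeling: RestLabeling, window_len: int, n_volumes: int
) -> float:
    """Alternative summary: percent of *volumes* covered by any task window.

    The window-level ``task_fraction`` is the primary statistic; this maps
    window labels back to volumes (a volume is task-labeled if any window
    containing it is task-labeled), for step-1 windows.
    """
    expected = n_volumes - window_len + 1
    if labeling.n_windows != expected:
        raise ValueError(
            f"{labeling.n_windows} windows inconsistent with {n_volumes} volumes "
            f"at window_len={window_len} (expected {expected})"
        )
    covered = np.zeros(n_volumes, dtype=bool)
    for start in np.flatnonzero(labeling.is_task):
        covered[start : start + window_len] = True
    return 100.0 * float(covered.mean())
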