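"""Nearest-template classification in spatiotemporal feature space.

The representational-similarity route to rest scoring: average the training
blocks of each class into a task and a non-task template, then label every
rest window by the smaller Euclidean distance.  Equidistant windows are
labeled non-task, mirroring the decoder's tie rule.  Distances are taken in
the (already z-normalized) feature space with no further scaling.

Nearest-template labeling by Euclidean distance is equivalent to a linear
rule, ``(t_task - t_non)' x - (||t_task||^2 - ||t_non||^2) / 2 > 0``; the
implementation is verified against that closed form in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import REPLAY, TASK
from .decoding import RestLabeling
from .features import ORDERING_TAG, SpatioTemporalSample, stack_samples

__all__ = [
    "TemplatePair",
    "build_templates",
    "classify_by_distance",
    "score_rest_rsa",
    "linear_form",
]

NON_TASK = "non_task"


@dataclass(frozen=True)
class TemplatePair:
    """Class-mean spatiotemporal patterns for task and non-task blocks."""

    task_template: np.ndarray
    nontask_template: np.ndarray
    n_task_blocks: int
    n_nontask_blocks: int
    window_len: int
    n_voxels: int

    def __post_init__(self) -> None:
        for name in ("task_template", "nontask_template"):
            vec = np.asarray(getattr(self, name), dtype=float)
            if vec.size != self.window_len * self.n_voxels:
                raise ValueError(f"{name} length does not match feature contract")
            if not np.isfinite(vec).all():
                raise ValueError(f"{name} contains non-finite values")
            object.__setattr__(self, name, vec)

    @property
    def feature_contract(self) -> tuple:
        return (self.window_len, self.n_voxels, ORDERING_TAG)


def build_templates(samples) -> TemplatePair:
    """Arithmetic mean of the training block vectors, per class."""
    X, labels = stack_samples(samples)
    task_rows = labels == TASK
    nontask_rows = labels == REPLAY
    if not task_rows.any() or not nontask_rows.any():
        raise ValueError(
            f"templates need both '{TASK}' and '{REPLAY}' samples, "
            f"got {sorted(set(labels))}"
        )
    return TemplatePair(
        task_template=X[task_rows].mean(axis=0),
        nontask_template=X[nontask_rows].mean(axis=0),
        n_task_blocks=int(task_rows.sum()),
        n_nontask_blocks=int(nontask_rows.sum()),
        window_len=samples[0].window_len,
        n_voxels=samples[0].n_voxels,
    )


def _distances(templates: TemplatePair, X: np.ndarray) -> tuple:
    d_task = np.linalg.norm(X - templates.task_template, axis=1)
    d_nontask = np.linalg.norm(X - templates.nontask_template, axis=1)
    return d_task, d_nontask


def classify_by_distance(
    window: SpatioTemporalSample, templates: TemplatePair
) -> str:
    """Label one window: task iff strictly closer to the task template."""
    if window.feature_contract != templates.feature_contract:
        raise ValueError(
            f"feature contract mismatch: templates {templates.feature_contract} "
            f"vs window {window.feature_contract}"
        )
    d_task, d_nontask = _distances(templates, window.vector[None, :])
    return TASK if d_task[0] < d_nontask[0] else NON_TASK


def score_rest_rsa(
    templates: TemplatePair, rest_windows, session_id: str | None = None
) -> RestLabeling:
    """Nearest-template labeling of all rest windows (same fraction contract
    as the SVM route)."""
    X, _ = stack_samples(rest_windows)
    if rest_windows[0].feature_contract != templates.feature_contract:
        raise ValueError(
            f"feature contract mismatch: templates {templates.feature_contract} "
            f"vs windows {rest_windows[0].feature_contract}"
        )
    d_task, d_nontask = _distances(templates, X)
    return RestLabeling(
        is_task=d_task < d_nontask,
        session_id=session_id or rest_windows[0].session_id,
        method="rsa",
    )


def linear_form(templates: TemplatePair) -> tuple:
    """Weights and bias of the equivalent linear rule (task iff w@x + b > 0)."""
    w = templates.task_template - templates.nontask_template
    b = -0.5 * (
        float(templates.task_template @ templates.task_template)
        - float(templates.nontask_template @ templates.nontask_template)
    )
    return w, b
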