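"""Spatiotemporal feature extraction: block epochs and sliding rest windows.

A sample is ``window_len`` consecutive volumes of the ROI flattened into a
single vector.  The feature-ordering contract is volume-major: vector index
``l * V + v`` is voxel ``v`` at window volume ``l`` (i.e. ``window.ravel()``
of the ``(L, V)`` block in C order).  Decoder weights and templates are
interpretable only under this ordering, so it is pinned by tests.

Training samples are one per block, shifted forward by the hemodynamic
delay (2 TRs = 6 s by default); rest samples are overlapping windows
advancing one volume at a time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import FLAG_ZNORMED, BlockEvents, PipelineOrderError, RoiTimeSeries

logger = logging.getLogger(__name__)

__all__ = [
    "SpatioTemporalSample",
    "SplitPlan",
    "epoch_blocks",
    "sliding_windows",
    "loso_splits",
    "stack_samples",
    "unflatten",
]

UNKNOWN = "unknown"
ORDERING_TAG = "volume-major"


@dataclass(frozen=True)
class SpatioTemporalSample:
    """One flattened window of ``window_len`` volumes x ``n_voxels`` voxels."""

    vector: np.ndarray
    label: str
    session_id: str
    start_volume: int  # 0-based index into the retained run
    window_len: int
    n_voxels: int

    def __post_init__(self) -> None:
        vec = np.asarray(self.vector, dtype=float)
        if vec.ndim != 1 or vec.size != self.window_len * self.n_voxels:
            raise ValueError(
                f"vector length {vec.size} != window_len*n_voxels "
                f"({self.window_len}*{self.n_voxels})"
            )
        if not np.isfinite(vec).all():
            raise ValueError("sample vector contains non-finite values")
        object.__setattr__(self, "vector", vec)

    @property
    def feature_contract(self) -> tuple:
        return (self.window_len, self.n_voxels, ORDERING_TAG)


@dataclass(frozen=True)
class SplitPlan:
    """Leave-one-session-out folds: each session is the test set exactly once."""

    folds: tuple  # of (train_session_ids: tuple, test_session_id)


def _window_sample(
    ts: RoiTimeSeries, start: int, window_len: int, label: str
) -> SpatioTemporalSample:
    block = ts.data[start : start + window_len]
    return SpatioTemporalSample(
        vector=block.ravel(),  # C order == volume-major contract
        label=label,
        session_id=ts.session_id,
        start_volume=start,
        window_len=window_len,
        n_voxels=ts.n_voxels,
    )


def epoch_blocks(
    ts: RoiTimeSeries,
    events: BlockEvents,
    shift_volumes: int = 2,
    window_len: int = 4,
) -> list:
    """One labeled sample per block, shifted by the hemodynamic delay.

    The sample for a block starting at retained volume ``r`` covers volumes
    ``r + shift_volumes .. r + shift_volumes + window_len - 1``.  Blocks
    whose shifted window falls outside the retained run are dropped (a
    fixed feature length is required), with the count logged.
    """
    if FLAG_ZNORMED not in ts.flags:
        raise PipelineOrderError("epoch_blocks requires a fully preprocessed series")
    samples = []
    n_dropped = 0
    for onset, duration, condition in events:
        if abs(onset / ts.tr_s - round(onset / ts.tr_s)) > 1e-9:
            raise ValueError(f"block onset {onset} s is not TR-aligned (TR {ts.tr_s} s)")
        if int(round(duration / ts.tr_s)) != window_len:
            raise ValueError(
                f"block duration {duration} s is not window_len={window_len} volumes"
            )
        start = int(round(onset / ts.tr_s)) - ts.n_discarded + shift_volumes
        if start < 0 or start + window_len > ts.n_volumes:
            n_dropped += 1
            continue
        samples.append(_window_sample(ts, start, window_len, condition))
    if n_dropped:
        logger.info(
            "epoch_blocks: dropped %d block(s) outside the retained run (%s)",
            n_dropped,
            ts.session_id,
        )
    return samples


def sliding_windows(
    ts: RoiTimeSeries, window_len: int = 4, step: int = 1
) -> list:
    """Unlabeled overlapping windows at starts 0, step, 2*step, ...

    Yields ``floor((T - window_len) / step) + 1`` windows.
    """
    if ts.n_volumes < window_len:
        raise ValueError(
            f"run of {ts.n_volumes} volumes is shorter than window_len={window_len}"
        )
    starts = range(0, ts.n_volumes - window_len + 1, step)
    return [_window_sample(ts, s, window_len, UNKNOWN) for s in starts]


def loso_splits(samples) -> SplitPlan:
    """Leave-one-session-out folds from labeled samples.

    Sessions are ordered by first appearance; each fold trains on all other
    sessions and tests on one.
    """
    session_ids = []
    for s in samples:
        if s.session_id not in session_ids:
            session_ids.append(s.session_id)
    if len(session_ids) < 2:
        raise ValueError("leave-one-session-out needs at least 2 sessions")
    folds = tuple(
        (tuple(sid for sid in session_ids if sid != test), test)
        for test in session_ids
    )
    return SplitPlan(folds)


def stack_samples(samples) -> tuple:
    """Stack samples into ``(X, labels)`` after checking a shared contract."""
    if not samples:
        raise ValueError("no samples to stack")
    contract = samples[0].feature_contract
    for s in samples:
        if s.feature_contract != contract:
            raise ValueError(
                f"feature contract mismatch: {s.feature_contract} vs {contract}"
            )
    X = np.vstack([s.vector for s in samples])
    labels = np.array([s.label for s in samples])
    return X, labels


def unflatten(sample: SpatioTemporalSample) -> np.ndarray:
    """Reshape a sample vector back to its ``(window_len, n_voxels)`` block."""
    return sample.vector.reshape(sample.window_len, sample.n_voxels)
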