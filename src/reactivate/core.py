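"""Shared containers: ROI time series, ROI masks, and block-event tables.

All downstream modules operate on these three objects.  A
:class:`RoiTimeSeries` is a plain ``T x V`` matrix (volumes by voxels) plus
the acquisition TR and a set of preprocessing flags that enforce the
pipeline order (discard -> high-pass -> z-score).  A :class:`RoiMask` pins
the canonical voxel ordering shared by every feature vector, decoder weight
vector, and template.  :class:`BlockEvents` is the in-memory form of a
BIDS-style events table (onset/duration in seconds, condition labels).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
import pandas as pd

TASK = "task"
REPLAY = "replay"
CONDITIONS = (TASK, REPLAY)

#: preprocessing flags, in required order
FLAG_DISCARDED = "discarded"
FLAG_FILTERED = "filtered"
FLAG_ZNORMED = "znormed"


class ConfigurationError(ValueError):
    """A configuration violates one of its design constraints."""


class PipelineOrderError(RuntimeError):
    """A preprocessing step was called out of its required order."""


@dataclass(frozen=True)
class RoiTimeSeries:
    """BOLD signal for one session's ROI voxels.

    Parameters
    ----------
    data
        ``(T, V)`` array, one row per volume, one column per voxel in the
        canonical mask ordering.  Arbitrary BOLD units.
    tr_s
        Repetition time in seconds.
    session_id, subject_id
        Provenance labels.
    flags
        Preprocessing steps already applied (see module constants).
    n_discarded
        Number of initial volumes already removed; used to convert
        event onsets (seconds from run start, pre-discard) into retained
        volume indices.
    constant_voxels
        Boolean mask of voxels that were constant at z-scoring time and
        were therefore zeroed (set by :func:`reactivate.preprocess.zscore_voxels`).
    """

    data: np.ndarray
    tr_s: float
    session_id: str = ""
    subject_id: str = ""
    flags: frozenset = frozenset()
    n_discarded: int = 0
    constant_voxels: np.ndarray | None = None

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2 or data.shape[0] < 1 or data.shape[1] < 1:
            raise ValueError(
                f"RoiTimeSeries.data must be a (T, V) matrix with T,V >= 1, "
                f"got shape {np.shape(self.data)}"
            )
        if not np.isfinite(data).all():
            raise ValueError("RoiTimeSeries.data contains non-finite values")
        if self.tr_s <= 0:
            raise ValueError(f"tr_s must be positive, got {self.tr_s}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "flags", frozenset(self.flags))

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    def with_(self, **kwargs) -> "RoiTimeSeries":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class BlockEvents:
    """Ordered condition blocks for one session.

    Onsets/durations are in seconds from the start of the run *including*
    any volumes later discarded (the BIDS convention).
    """

    onsets_s: np.ndarray
    durations_s: np.ndarray
    conditions: tuple
    session_id: str = ""

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onsets_s, dtype=float)
        durations = np.asarray(self.durations_s, dtype=float)
        conditions = tuple(self.conditions)
        if not (len(onsets) == len(durations) == len(conditions)):
            raise ValueError("onsets, durations and conditions must have equal length")
        if np.any(durations <= 0):
            raise ValueError("block durations must be positive")
        if np.any(onsets < 0):
            raise ValueError("block onsets must be non-negative")
        if np.any(np.diff(onsets) < 0):
            raise ValueError("block onsets must be sorted")
        object.__setattr__(self, "onsets_s", onsets)
        object.__setattr__(self, "durations_s", durations)
        object.__setattr__(self, "conditions", conditions)

    def __len__(self) -> int:
        return len(self.onsets_s)

    def __iter__(self) -> Iterator[tuple]:
        return iter(zip(self.onsets_s, self.durations_s, self.conditions))

    def for_condition(self, condition: str) -> "BlockEvents":
        keep = [i for i, c in enumerate(self.conditions) if c == condition]
        return BlockEvents(
            self.onsets_s[keep],
            self.durations_s[keep],
            tuple(self.conditions[i] for i in keep),
            session_id=self.session_id,
        )

    def to_frame(self) -> pd.DataFrame:
        """BIDS-style events table (onset, duration, trial_type)."""
        return pd.DataFrame(
            {
                "onset": self.onsets_s,
                "duration": self.durations_s,
                "trial_type": list(self.conditions),
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, session_id: str = "") -> "BlockEvents":
        return cls(
            frame["onset"].to_numpy(float),
            frame["duration"].to_numpy(float),
            tuple(frame["trial_type"]),
            session_id=session_id,
        )


@dataclass(frozen=True)
class RoiMask:
    """Binary ROI mask as an explicit, ordered voxel list on a 3D grid.

    The order of ``voxel_indices`` is the canonical voxel ordering: column
    ``v`` of every :class:`RoiTimeSeries` and every feature vector refers to
    ``voxel_indices[v]``.
    """

    grid_shape: tuple
    voxel_indices: np.ndarray  # (V, 3) integer coordinates, 0-based

    def __post_init__(self) -> None:
        idx = np.asarray(self.voxel_indices, dtype=int)
        shape = tuple(int(s) for s in self.grid_shape)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"grid_shape must be 3 positive dimensions, got {shape}")
        if idx.ndim != 2 or idx.shape[1] != 3 or idx.shape[0] < 1:
            raise ValueError("voxel_indices must be a non-empty (V, 3) array")
        if np.any(idx < 0) or np.any(idx >= np.array(shape)):
            raise ValueError("voxel_indices out of grid bounds")
        if len(np.unique(idx, axis=0)) != idx.shape[0]:
            raise ValueError("voxel_indices contains duplicates")
        object.__setattr__(self, "grid_shape", shape)
        object.__setattr__(self, "voxel_indices", idx)

    @property
    def n_voxels(self) -> int:
        return self.voxel_indices.shape[0]

    def to_volume(self) -> np.ndarray:
        """Binary 3D array with ones at the mask voxels."""
        vol = np.zeros(self.grid_shape, dtype=np.uint8)
        vol[tuple(self.voxel_indices.T)] = 1
        return vol

    @classmethod
    def from_volume(cls, volume: np.ndarray) -> "RoiMask":
        """Build a mask from a binary 3D array (C-order voxel ordering)."""
        idx = np.argwhere(np.asarray(volume) != 0)
        if idx.size == 0:
            raise ValueError("mask volume contains no voxels")
        return cls(tuple(volume.shape), idx)

    @classmethod
    def cube_for(cls, n_voxels: int) -> "RoiMask":
        """Smallest cubic grid holding ``n_voxels``, filled in C order.

        This is the default embedding used when writing simulated ROI data
        to NIfTI.
        """
        if n_voxels < 1:
            raise ValueError("n_voxels must be >= 1")
        side = int(np.ceil(n_voxels ** (1.0 / 3.0)))
        while side**3 < n_voxels:  # guard against fp rounding of the cube root
            side += 1
        coords = np.array(list(np.ndindex(side, side, side))[:n_voxels])
        return cls((side, side, side), coords)
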