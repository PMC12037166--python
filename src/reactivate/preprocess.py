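"""Temporal preprocessing of ROI time series, in the order the decoder expects.

The pipeline is: discard initial volumes (T1 equilibration), DCT high-pass
filter (cutoff period 128 s by default), per-voxel z-normalization within
the run.  Each step sets a flag on the series and refuses to run before its
predecessor, so out-of-order calls fail loudly rather than silently
changing the statistics the decoder is trained on.
"""

from __future__ import annotations

import numpy as np

from .core import (
    FLAG_DISCARDED,
    FLAG_FILTERED,
    FLAG_ZNORMED,
    PipelineOrderError,
    RoiMask,
    RoiTimeSeries,
)

__all__ = [
    "discard_initial",
    "dct_highpass",
    "n_drift_regressors",
    "dct_drift_basis",
    "zscore_voxels",
    "preprocess_session",
    "extract_roi",
]


def discard_initial(ts: RoiTimeSeries, n: int = 3) -> RoiTimeSeries:
    """Drop the first ``n`` volumes (scanner equilibration period)."""
    if n < 0:
        raise ValueError("n must be non-negative")
    if n >= ts.n_volumes:
        raise ValueError(f"cannot discard {n} of {ts.n_volumes} volumes")
    return ts.with_(
        data=ts.data[n:],
        flags=ts.flags | {FLAG_DISCARDED},
        n_discarded=ts.n_discarded + n,
    )


def n_drift_regressors(n_volumes: int, tr_s: float, cutoff_s: float) -> int:
    """Number of DCT drift regressors: K = floor(2 * T * TR / cutoff)."""
    return int(np.floor(2.0 * n_volumes * tr_s / cutoff_s))


def dct_drift_basis(n_volumes: int, tr_s: float, cutoff_s: float) -> np.ndarray:
    """DCT-II drift basis (without intercept): columns cos(pi k (2t+1) / 2T).

    Includes all k = 1..K whose period exceeds the cutoff, with
    K = floor(2 T TR / cutoff) — the SPM high-pass convention.
    """
    T = n_volumes
    K = n_drift_regressors(T, tr_s, cutoff_s)
    t = np.arange(T)
    return np.cos(
        np.pi * np.arange(1, K + 1)[None, :] * (2 * t[:, None] + 1) / (2.0 * T)
    )


def dct_highpass(ts: RoiTimeSeries, cutoff_s: float = 128.0) -> RoiTimeSeries:
    """Remove slow drift: residualize each voxel on the DCT drift basis.

    The output is the residual of projecting each voxel's series onto the
    span of {constant} union {DCT drift regressors with period > cutoff},
    so the mean is removed as well.
    """
    if FLAG_DISCARDED not in ts.flags:
        raise PipelineOrderError("dct_highpass requires discard_initial first")
    if cutoff_s <= 2.0 * ts.tr_s:
        raise ValueError(
            f"cutoff_s={cutoff_s} must exceed twice the TR ({2 * ts.tr_s})"
        )
    basis = dct_drift_basis(ts.n_volumes, ts.tr_s, cutoff_s)
    X = np.column_stack([np.ones(ts.n_volumes), basis])
    coefs, *_ = np.linalg.lstsq(X, ts.data, rcond=None)
    resid = ts.data - X @ coefs
    return ts.with_(data=resid, flags=ts.flags | {FLAG_FILTERED})


def zscore_voxels(ts: RoiTimeSeries) -> RoiTimeSeries:
    """Standardize each voxel by its own within-run mean and sd (ddof=1).

    Voxels with (numerically) zero variance are set to all zeros and
    recorded in ``constant_voxels`` — never NaN, so decoder input stays
    finite.  Idempotent.
    """
    if FLAG_FILTERED not in ts.flags:
        raise PipelineOrderError("zscore_voxels requires dct_highpass first")
    mu = ts.data.mean(axis=0)
    sd = ts.data.std(axis=0, ddof=1)
    # scale-aware tolerance: residual ripple of a constant input is O(eps * scale)
    tol = 1e-8 * max(1.0, float(np.abs(ts.data).max()))
    constant = sd <= tol
    safe_sd = np.where(constant, 1.0, sd)
    z = (ts.data - mu) / safe_sd
    z[:, constant] = 0.0
    return ts.with_(
        data=z, flags=ts.flags | {FLAG_ZNORMED}, constant_voxels=constant
    )


def preprocess_session(
    ts: RoiTimeSeries, discard: int = 3, cutoff_s: float = 128.0
) -> RoiTimeSeries:
    """Full temporal pipeline: discard -> high-pass -> z-score."""
    return zscore_voxels(dct_highpass(discard_initial(ts, discard), cutoff_s))


def extract_roi(
    volumes: np.ndarray,
    mask: RoiMask,
    tr_s: float,
    session_id: str = "",
    subject_id: str = "",
) -> RoiTimeSeries:
    """Extract a ``T x V`` matrix from a 4D image in canonical mask order.

    ``volumes`` is ``(X, Y, Z, T)``; column ``v`` of the result is the
    series of voxel ``mask.voxel_indices[v]``.
    """
    volumes = np.asarray(volumes)
    if volumes.ndim != 4:
        raise ValueError(f"expected a 4D (X, Y, Z, T) array, got shape {volumes.shape}")
    if tuple(volumes.shape[:3]) != tuple(mask.grid_shape):
        raise ValueError(
            f"image grid {volumes.shape[:3]} does not match mask grid {mask.grid_shape}"
        )
    idx = mask.voxel_indices
    data = volumes[idx[:, 0], idx[:, 1], idx[:, 2], :].T
    return RoiTimeSeries(
        np.ascontiguousarray(data, dtype=float),
        tr_s,
        session_id=session_id,
        subject_id=subject_id,
    )
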