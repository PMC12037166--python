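"""Minimal single-subject GLM: HRF-convolved boxcars, OLS, t-contrasts.

This is a sanity-check analysis for the synthetic data — it verifies that a
simulated task session actually contains the planted condition activation.
Variance estimation is plain OLS (no AR prewhitening) and no
multiple-comparison correction is applied; group-level inference is out of
scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats

from .core import CONDITIONS, BlockEvents, RoiTimeSeries
from .preprocess import dct_drift_basis
from .synthetic import condition_regressor

__all__ = ["DesignMatrix", "build_design", "fit_contrast"]


@dataclass(frozen=True)
class DesignMatrix:
    """OLS design: one HRF-convolved column per condition + drift + intercept."""

    matrix: np.ndarray
    column_names: tuple
    tr_s: float

    def __post_init__(self) -> None:
        if self.matrix.shape[1] != len(self.column_names):
            raise ValueError("column_names must match matrix columns")
        if np.linalg.matrix_rank(self.matrix) < self.matrix.shape[1]:
            raise ValueError("design matrix is rank deficient")

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.column_names.index(name)]

    def contrast(self, weights: dict) -> np.ndarray:
        """Build a contrast vector from a {column_name: weight} mapping."""
        c = np.zeros(len(self.column_names))
        for name, w in weights.items():
            c[self.column_names.index(name)] = w
        return c


def build_design(
    events: BlockEvents,
    n_volumes: int,
    tr_s: float,
    n_discarded: int = 0,
    hp_cutoff_s: float = 128.0,
) -> DesignMatrix:
    """Design matrix for a retained run of ``n_volumes`` volumes.

    Condition regressors are built on the full pre-discard timeline (event
    onsets are in seconds from run start) and the first ``n_discarded``
    rows are then dropped, mirroring the data pipeline.  DCT drift columns
    at the given cutoff plus an intercept are appended.  Conditions with no
    events contribute no column.
    """
    total = n_volumes + n_discarded
    cols, names = [], []
    for condition in CONDITIONS:
        reg = condition_regressor(events, condition, total, tr_s)[n_discarded:]
        if np.any(reg != 0.0):
            cols.append(reg)
            names.append(condition)
    drift = dct_drift_basis(n_volumes, tr_s, hp_cutoff_s)
    for k in range(drift.shape[1]):
        cols.append(drift[:, k])
        names.append(f"drift-{k + 1}")
    cols.append(np.ones(n_volumes))
    names.append("intercept")
    return DesignMatrix(np.column_stack(cols), tuple(names), tr_s)


def fit_contrast(
    ts: RoiTimeSeries, design: DesignMatrix, contrast: np.ndarray
) -> np.ndarray:
    """Per-voxel OLS t-values for a contrast of design columns.

    t = c'beta / sqrt(sigma2 * c'(X'X)^-1 c), df = T - rank(X).  Voxels fit
    exactly (zero residual) report signed infinity; a zero numerator over
    zero variance reports 0.
    """
    X = design.matrix
    if X.shape[0] != ts.n_volumes:
        raise ValueError(
            f"design has {X.shape[0]} rows but series has {ts.n_volumes} volumes"
        )
    contrast = np.asarray(contrast, dtype=float)
    if contrast.shape != (X.shape[1],):
        raise ValueError(
            f"contrast length {contrast.shape} does not match {X.shape[1]} columns"
        )
    xtx = X.T @ X
    if np.linalg.cond(xtx) > 1e12:
        raise np.linalg.LinAlgError("X'X is singular or near-singular")
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ (X.T @ ts.data)
    resid = ts.data - X @ beta
    df = ts.n_volumes - np.linalg.matrix_rank(X)
    sigma2 = (resid**2).sum(axis=0) / df
    num = contrast @ beta
    denom = np.sqrt(sigma2 * (contrast @ xtx_inv @ contrast))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = num / denom
    return np.where(np.isnan(t), 0.0, t)


def contrast_p_values(t: np.ndarray, df: int) -> np.ndarray:
    """Two-sided p-values for OLS t-values."""
    return 2.0 * _stats.t.sf(np.abs(t), df)
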