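"""Connectivity estimation from regional BOLD-like time series.

Three interaction objects are derived from a region × time matrix:

* static functional connectivity — full-series Pearson correlation,
* first-order vector-autoregression coefficients (effective connectivity),
* a sliding-window sequence of Pearson correlation matrices
  (time-resolved functional connectivity).

Series are stored regions-in-rows, frames-in-columns.  Frame indices are
0-based and windows are half-open ``[start, start + window)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "TimeSeriesData",
    "ConnectivityMatrix",
    "ARModel",
    "preprocess_series",
    "static_fc",
    "ar1_fc",
    "sliding_window_fc",
]

#: connectivity kinds
STATIC_CORRELATION = "static_correlation"
AUTOREGRESSION = "autoregression"
WINDOW_CORRELATION = "window_correlation"

_VAR_FLOOR = 1e-12


@dataclass
class TimeSeriesData:
    """A single subject's region × frame state trajectory x(t).

    Parameters
    ----------
    values
        Array of shape ``(n_regions, n_frames)``.
    tr_seconds
        Sampling interval of one frame; informational only — all horizons
        in this package are expressed in frame (TR) units.
    region_ids
        Ordered region labels; defaults to ``r000, r001, ...``.
    normalized
        True once each region has been z-scored to mean 0, variance 1.
    """

    values: np.ndarray
    tr_seconds: float = 0.72
    region_ids: list[str] = field(default_factory=list)
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D region × frame array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contains non-finite values")
        if not self.region_ids:
            self.region_ids = [f"r{i:03d}" for i in range(self.n_regions)]
        if len(self.region_ids) != self.n_regions:
            raise ValueError("region_ids length does not match row count")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclass
class ConnectivityMatrix:
    """A region × region interaction estimate of a given kind."""

    matrix: np.ndarray
    kind: str
    window_span: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n, m = self.matrix.shape
        if n != m:
            raise ValueError("connectivity matrix must be square")

    @property
    def n_regions(self) -> int:
        return self.matrix.shape[0]


@dataclass
class ARModel:
    """First-order vector autoregression fit x(t) ≈ A x(t-1).

    ``coefficients`` is the full N × N coupling matrix estimated jointly by
    multi-output ordinary least squares; ``residuals`` hold the innovation
    estimates for the fitted frames, ``fit_r2`` the per-region variance
    explained.  ``rank_deficient`` flags a pseudo-inverse solve.
    """

    coefficients: np.ndarray
    residuals: np.ndarray
    fit_r2: np.ndarray
    rank_deficient: bool = False

    def as_connectivity(self) -> ConnectivityMatrix:
        return ConnectivityMatrix(self.coefficients, kind=AUTOREGRESSION)


def preprocess_series(raw: TimeSeriesData, n_discard: int = 50) -> TimeSeriesData:
    """Drop initial equilibration frames and z-score each region.

    The first ``n_discard`` frames are removed (suppressing scanner
    equilibration transients in real data) and every region is normalized
    to mean 0, variance 1 over the remaining frames.
    """
    if raw.n_frames <= n_discard:
        raise ValueError(
            f"series has {raw.n_frames} frames, cannot discard {n_discard}"
        )
    vals = raw.values[:, n_discard:]
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, keepdims=True)
    dead = np.nonzero(sd.ravel() < _VAR_FLOOR)[0]
    if dead.size:
        names = ", ".join(raw.region_ids[i] for i in dead[:5])
        raise ValueError(f"cannot z-score constant region(s): {names}")
    out = (vals - mean) / sd
    return replace(raw, values=out, normalized=True)


def static_fc(ts: TimeSeriesData) -> ConnectivityMatrix:
    """Full-series Pearson correlation matrix (static FC)."""
    if ts.n_frames < 3:
        raise ValueError("need at least 3 frames for a correlation estimate")
    F = _safe_corrcoef(ts.values)
    return ConnectivityMatrix(F, kind=STATIC_CORRELATION)


def ar1_fc(ts: TimeSeriesData) -> ARModel:
    """Fit the first-order vector autoregression x(t) = A x(t-1) + ε(t).

    All regions are regressed jointly on the full lagged state vector
    (multi-output ordinary least squares), so A minimizes
    ``sum_t || x(t) - A x(t-1) ||^2``.  A rank-deficient lagged design is
    solved through the pseudo-inverse and flagged.
    """
    n, T = ts.values.shape
    if T < n + 2:
        raise ValueError("series too short to identify the AR coefficients")
    X = ts.values[:, :-1].T  # (T-1, n) lagged states
    Y = ts.values[:, 1:].T  # (T-1, n) current states
    coef_T, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    coefficients = coef_T.T
    rank_deficient = rank < n
    if rank_deficient:
        warnings.warn(
            "lagged design is rank deficient; coefficients are the "
            "minimum-norm least-squares solution",
            RuntimeWarning,
            stacklevel=2,
        )
    residuals = Y.T - coefficients @ X.T
    total = Y.var(axis=0)
    resid_var = residuals.var(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fit_r2 = np.where(total > _VAR_FLOOR, 1.0 - resid_var / total, 0.0)
    return ARModel(coefficients, residuals, fit_r2, rank_deficient)


def sliding_window_fc(
    ts: TimeSeriesData, window: int = 60, step: int = 10
) -> list[ConnectivityMatrix]:
    """Rectangular sliding-window Pearson correlations.

    Windows start at 0, step, 2*step, ...; each covers the half-open frame
    interval ``[start, start + window)``; a trailing partial window is
    discarded.  Correlations are computed with window-local means and
    variances (the windowed signal is re-centred, not reusing any global
    z-scoring).
    """
    if window < 2 or step < 1:
        raise ValueError("window must be >= 2 and step >= 1")
    T = ts.n_frames
    if T < window:
        raise ValueError(f"series of {T} frames is shorter than window {window}")
    out: list[ConnectivityMatrix] = []
    for start in range(0, T - window + 1, step):
        block = ts.values[:, start : start + window]
        F = _safe_corrcoef(block)
        out.append(
            ConnectivityMatrix(
                F, kind=WINDOW_CORRELATION, window_span=(start, start + window)
            )
        )
    return out


def _safe_corrcoef(values: np.ndarray) -> np.ndarray:
    """Pearson correlation with near-constant rows mapped to 0 correlation."""
    sd = values.std(axis=1)
    dead = sd < _VAR_FLOOR
    if dead.any():
        warnings.warn(
            f"{int(dead.sum())} near-constant region(s) in window; their "
            "correlations are set to 0",
            RuntimeWarning,
            stacklevel=3,
        )
        vals = values.copy()
        vals[dead] = 0.0
        with np.errstate(invalid="ignore"):
            F = np.corrcoef(vals)
        F[dead, :] = 0.0
        F[:, dead] = 0.0
        np.fill_diagonal(F, 1.0)
        return F
    F = np.corrcoef(values)
    np.fill_diagonal(F, 1.0)
    return np.clip(F, -1.0, 1.0)
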