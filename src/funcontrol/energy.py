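"""Minimum control energy under static and snapshot-switching dynamics.

For a time-invariant interaction matrix A, the minimum-energy transfer
x0 -> xf over a horizon tau is

    E_s = (1/2) d^T W(tau)^{-1} d,        d = xf - e^{A tau} x0,

with W the finite-horizon controllability Gramian restricted to the
chosen control set.  For a piecewise-constant (snapshot) system with
matrices A_1..A_M and durations tau_1..tau_M the drift term is the
ordered product of snapshot exponentials and the Gramian is assembled
from per-snapshot Gramians propagated through the remaining snapshots:

    W_dyn = sum_m S_m W_m S_m^T,   S_m = e^{A_M tau_M} ... e^{A_{m+1} tau_{m+1}},

with S_M = I.  Shuffle nulls permute the snapshot matrices while keeping
durations attached to positions, isolating the effect of reconfiguration
order on the energy budget.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from .connectivity import ConnectivityMatrix, TimeSeriesData
from .control import NormalizedInteraction, finite_horizon_gramian, laplacian_normalize

__all__ = [
    "TransitionSpec",
    "TemporalSystem",
    "EnergyResult",
    "ShuffleNullResult",
    "static_min_energy",
    "temporal_min_energy",
    "build_temporal_system",
    "segment_windows",
    "extract_states",
    "shuffle_null",
    "tau_sweep",
]

_REACH_TOL = 1e-6
_COND_LIMIT = 1e12


@dataclass
class TransitionSpec:
    """Endpoint states and horizon of one transition."""

    x0: np.ndarray
    xf: np.ndarray
    tau_s: float

    def __post_init__(self) -> None:
        self.x0 = np.asarray(self.x0, dtype=float)
        self.xf = np.asarray(self.xf, dtype=float)
        if self.x0.shape != self.xf.shape:
            raise ValueError("x0 and xf must have the same dimension")
        if not (np.all(np.isfinite(self.x0)) and np.all(np.isfinite(self.xf))):
            raise ValueError("transition states must be finite")
        if self.tau_s <= 0:
            raise ValueError("horizon must be positive")


@dataclass
class TemporalSystem:
    """Ordered snapshot interaction matrices with durations and control set."""

    snapshots: list[NormalizedInteraction]
    durations: np.ndarray
    B: np.ndarray
    window_spans: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.durations = np.asarray(self.durations, dtype=float)
        if len(self.snapshots) != self.durations.size:
            raise ValueError("one duration per snapshot required")
        if np.any(self.durations <= 0):
            raise ValueError("snapshot durations must be positive")

    @property
    def M(self) -> int:
        return len(self.snapshots)

    @property
    def total_horizon(self) -> float:
        return float(self.durations.sum())


@dataclass
class EnergyResult:
    energy: float
    d: np.ndarray
    gramian_cond: float
    paradigm: str


@dataclass
class ShuffleNullResult:
    """Observed-order energy against its snapshot-permutation null."""

    observed_energy: float
    null_energies: np.ndarray
    seed: int

    @property
    def log_inflation(self) -> float:
        """mean(log E_r) - log E_d: positive when shuffling costs energy."""
        return float(np.mean(np.log(self.null_energies)) - np.log(self.observed_energy))


def _energy_from_gramian(
    W: np.ndarray, d: np.ndarray, paradigm: str
) -> EnergyResult:
    cond = float(np.linalg.cond(W))
    if cond > _COND_LIMIT or not np.isfinite(cond):
        Winv = np.linalg.pinv(W, rcond=1e-12, hermitian=True)
        # uncontrollable directions: d must lie in range(W)
        residual = d - W @ (Winv @ d)
        scale = np.linalg.norm(d)
        if scale > 0 and np.linalg.norm(residual) / scale > _REACH_TOL:
            raise ValueError("target unreachable with given control set")
        warnings.warn(
            f"Gramian condition number {cond:.2e}; pseudo-inverse energy",
            RuntimeWarning,
            stacklevel=3,
        )
        energy = 0.5 * float(d @ (Winv @ d))
    else:
        energy = 0.5 * float(d @ np.linalg.solve(W, d))
    return EnergyResult(max(energy, 0.0), d, cond, paradigm)


def static_min_energy(
    A: np.ndarray, B: np.ndarray, spec: TransitionSpec
) -> EnergyResult:
    """Minimum energy of the transition under time-invariant dynamics."""
    A = np.asarray(A, dtype=float)
    d = spec.xf - expm(A * spec.tau_s) @ spec.x0
    W = finite_horizon_gramian(A, B, spec.tau_s)
    return _energy_from_gramian(W, d, "static")


def temporal_min_energy(
    system: TemporalSystem, spec: TransitionSpec
) -> EnergyResult:
    """Minimum energy under the snapshot-switching dynamics.

    Later snapshots multiply on the left in every exponential product;
    with a single snapshot this reduces exactly to the static computation
    on that snapshot's duration.
    """
    mats = [s.A for s in system.snapshots]
    taus = system.durations
    Phi = [expm(A * t) for A, t in zip(mats, taus)]
    n = mats[0].shape[0]
    # S_m: product of snapshot exponentials after snapshot m (S_M = I)
    S = [np.eye(n)]
    for m in range(system.M - 1, 0, -1):
        S.append(S[-1] @ Phi[m])
    S = S[::-1]
    drift = S[0] @ Phi[0]
    d = spec.xf - drift @ spec.x0
    W_dyn = np.zeros((n, n))
    for m in range(system.M):
        Wm = finite_horizon_gramian(mats[m], system.B, taus[m])
        W_dyn += S[m] @ Wm @ S[m].T
    W_dyn = 0.5 * (W_dyn + W_dyn.T)
    return _energy_from_gramian(W_dyn, d, "temporal")


def segment_windows(
    n_frames: int, window: int = 60
) -> list[tuple[int, int]]:
    """Consecutive non-overlapping ``[start, start+window)`` segments
    covering as much of the series as whole windows allow."""
    if n_frames < window:
        raise ValueError(f"{n_frames} frames cannot hold a {window}-frame window")
    return [(s, s + window) for s in range(0, n_frames - window + 1, window)]


def build_temporal_system(
    windows: list[ConnectivityMatrix],
    B: np.ndarray,
    end_duration: float = 30.0,
    mid_duration: float = 60.0,
    stabilize: bool = True,
) -> TemporalSystem:
    """Normalize windowed connectivity into a snapshot-switching system.

    The first and last snapshots get ``end_duration`` (half a window on
    each side, consistent with states defined at window centers) and the
    middle snapshots ``mid_duration``; the paired static horizon is the
    sum of all durations.
    """
    if not windows:
        raise ValueError("need at least one window")
    if len(windows) == 1:
        warnings.warn(
            "single-snapshot system: the temporal paradigm degenerates to "
            "a static one",
            RuntimeWarning,
            stacklevel=2,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        snaps = [laplacian_normalize(w, stabilize=stabilize) for w in windows]
    M = len(snaps)
    if M == 1:
        durations = np.array([end_duration])
    else:
        durations = np.full(M, mid_duration)
        durations[0] = durations[-1] = end_duration
    spans = [w.window_span for w in windows if w.window_span is not None]
    return TemporalSystem(snaps, durations, B, spans if len(spans) == M else [])


def extract_states(
    ts: TimeSeriesData,
    first_span: tuple[int, int],
    last_span: tuple[int, int],
    mode: str = "window_center_mean10",
) -> tuple[np.ndarray, np.ndarray]:
    """Endpoint states from the first and last snapshot of a segment.

    ``window_center_mean10`` averages the central 10 frames of each
    window (for a 60-frame window starting at s: frames s+25 .. s+34);
    ``endpoint_value`` takes the first frame of the first window and the
    last frame of the last window.
    """
    if mode == "window_center_mean10":
        return (
            _center_mean(ts.values, first_span, 10),
            _center_mean(ts.values, last_span, 10),
        )
    if mode == "endpoint_value":
        return ts.values[:, first_span[0]].copy(), ts.values[:, last_span[1] - 1].copy()
    raise ValueError(f"unknown state-extraction mode: {mode}")


def _center_mean(values: np.ndarray, span: tuple[int, int], k: int) -> np.ndarray:
    start, stop = span
    width = stop - start
    if width < k:
        raise ValueError(f"window of {width} frames too short for central {k}")
    lo = start + (width - k) // 2
    return values[:, lo : lo + k].mean(axis=1)


def shuffle_null(
    system: TemporalSystem,
    spec: TransitionSpec,
    n_perm: int = 20,
    seed: int = 0,
) -> ShuffleNullResult:
    """Snapshot-order permutation null of the temporal energy.

    Permutations act on the snapshot matrices only; durations stay
    attached to their positions (the two ends keep the end duration).
    Permutations are sampled uniformly, without forcing distinctness.
    """
    if system.M < 2:
        raise ValueError("shuffle null needs at least two snapshots")
    observed = temporal_min_energy(system, spec)
    rng = np.random.default_rng(seed)
    nulls = np.empty(n_perm)
    for p in range(n_perm):
        order = rng.permutation(system.M)
        shuffled = TemporalSystem(
            [system.snapshots[i] for i in order], system.durations, system.B
        )
        nulls[p] = temporal_min_energy(shuffled, spec).energy
    return ShuffleNullResult(observed.energy, nulls, seed)


def transition_experiment(
    ts: TimeSeriesData,
    pair: tuple[int, int],
    B: np.ndarray,
    window: int = 60,
    end_duration: float = 30.0,
    mid_duration: float = 60.0,
    state_mode: str = "window_center_mean10",
) -> tuple[TemporalSystem, TransitionSpec, np.ndarray]:
    """Build the paired static/temporal systems for one sampled transition.

    The segment between the sampled frame pair is cut into consecutive
    non-overlapping windows; the temporal system normalizes each window's
    correlation matrix, the static system normalizes the correlation of
    the whole segment, and the endpoint states come from the first and
    last window.  Returns (temporal system, transition spec, static A);
    the spec's horizon is the temporal system's total duration, so the
    two paradigms are compared on equal time.
    """
    from .connectivity import sliding_window_fc, static_fc

    start, end = pair
    if end - start < 2 * window:
        raise ValueError("segment too short for a two-snapshot experiment")
    segment = TimeSeriesData(ts.values[:, start:end], tr_seconds=ts.tr_seconds)
    windows = sliding_window_fc(segment, window=window, step=window)
    system = build_temporal_system(
        windows, B, end_duration=end_duration, mid_duration=mid_duration
    )
    x0, xf = extract_states(
        segment, windows[0].window_span, windows[-1].window_span, mode=state_mode
    )
    spec = TransitionSpec(x0, xf, system.total_horizon)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        static_A = laplacian_normalize(static_fc(segment)).A
    return system, spec, static_A


def tau_sweep(
    system: TemporalSystem,
    static_A: np.ndarray,
    x0: np.ndarray,
    xf: np.ndarray,
    tau_values: np.ndarray | list[float],
) -> list[dict]:
    """Energy of both paradigms across a range of total horizons.

    For each total horizon tau_s the static system runs on tau_s and the
    temporal system divides it evenly, tau_d = tau_s / M per snapshot.
    Returns one row per horizon with keys tau_s, E_s, E_d.
    """
    tau_values = np.asarray(tau_values, dtype=float)
    if np.any(tau_values <= 0):
        raise ValueError("tau values must be positive")
    rows = []
    for tau_s in tau_values:
        spec = TransitionSpec(x0, xf, float(tau_s))
        even = TemporalSystem(
            system.snapshots,
            np.full(system.M, tau_s / system.M),
            system.B,
        )
        rows.append(
            {
                "tau_s": float(tau_s),
                "E_s": static_min_energy(static_A, system.B, spec).energy,
                "E_d": temporal_min_energy(even, spec).energy,
            }
        )
    return rows
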