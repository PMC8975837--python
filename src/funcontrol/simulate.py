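"""Synthetic multi-subject BOLD-like data with known switching dynamics.

The generator emulates the statistical structure the downstream analysis
assumes: piecewise-stationary first-order vector-autoregressive series
whose coupling matrix drifts slowly (and in a fixed, non-random order)
between a small number of epochs, with a block-modular community
structure, between-subject variability, and behavioral scores carrying a
planted linear dependence on derived regional features.

Within epoch e a subject's states follow

    x(t) = C_e x(t-1) + eta(t),      eta(t) ~ N(0, noise_sd^2 I),

where consecutive epoch matrices are convex interpolations toward fresh
random modular targets, rescaled to a common spectral radius so every
segment is stationary.  With ``noise_sd = 0`` the recurrence is exact and
the trajectory decays deterministically from a random initial state —
the regime in which least squares recovers C_e to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectivity import TimeSeriesData

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_switching_lds",
    "generate_behavior_scores",
    "noise_sd_for_target_r",
    "sample_transition_endpoints",
    "default_partition",
]


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror a desk-scale analog of a resting-state cohort: 1200
    frames per run, 60-frame windows downstream, a handful of slowly
    drifting connectivity regimes, and modular signed coupling.
    """

    n_subjects: int = 20
    n_regions: int = 30
    n_timepoints: int = 1200
    n_modules: int = 4
    n_epochs: int = 6
    drift_rate: float = 0.3
    ar_spectral_radius: float = 0.9
    noise_sd: float = 1.0
    subject_sd: float = 0.1
    module_assignment: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 2:
            raise ValueError("need at least 2 regions")
        if not 0.0 < self.ar_spectral_radius < 1.0:
            raise ValueError("ar_spectral_radius must lie in (0, 1)")
        if not 0.0 <= self.drift_rate <= 1.0:
            raise ValueError("drift_rate must lie in [0, 1]")
        if self.n_timepoints < 60:
            raise ValueError("need at least 60 frames")
        if self.n_epochs < 1:
            raise ValueError("need at least one epoch")
        if self.noise_sd < 0 or self.subject_sd < 0:
            raise ValueError("noise scales must be nonnegative")
        if self.module_assignment is None:
            self.module_assignment = default_partition(self.n_regions, self.n_modules)
        else:
            self.module_assignment = np.asarray(self.module_assignment, dtype=int)
            if self.module_assignment.shape != (self.n_regions,):
                raise ValueError("module_assignment must label every region")


@dataclass
class GroundTruth:
    """What the generator actually used, for recovery tests."""

    epoch_coefficient_matrices: list[np.ndarray]
    epoch_boundaries: np.ndarray  # frame index where each epoch starts, plus T
    module_assignment: np.ndarray
    subject_matrices: list[list[np.ndarray]] = field(default_factory=list)


@dataclass
class BehaviorScores:
    scores: np.ndarray
    weights: np.ndarray
    noise_sd: float
    theoretical_r: float


def default_partition(n_regions: int, n_modules: int) -> np.ndarray:
    """Contiguous, near-equal community blocks."""
    return np.sort(np.arange(n_regions) % n_modules)


def _modular_matrix(
    rng: np.random.Generator, assignment: np.ndarray, radius: float
) -> np.ndarray:
    """Random signed block-modular coupling, rescaled to spectral radius."""
    n = assignment.size
    same = assignment[:, None] == assignment[None, :]
    # positive within-module coupling, weaker mixed-sign between-module
    within = np.abs(rng.normal(0.0, 1.0, (n, n)))
    between = rng.normal(0.0, 0.35, (n, n))
    C = np.where(same, within, between)
    np.fill_diagonal(C, np.abs(rng.normal(1.5, 0.2, n)))
    return _rescale_radius(C, radius)


def _rescale_radius(C: np.ndarray, radius: float) -> np.ndarray:
    rho = np.max(np.abs(np.linalg.eigvals(C)))
    if rho <= 0:
        raise ValueError("degenerate coefficient matrix; cannot set spectral radius")
    return C * (radius / rho)


def generate_switching_lds(
    config: SyntheticConfig,
) -> tuple[list[TimeSeriesData], GroundTruth]:
    """Simulate the multi-subject switching linear dynamical system.

    Returns one :class:`TimeSeriesData` per subject plus the ground truth
    (population epoch matrices, per-subject matrices, epoch boundaries).
    Generation is a pure function of the config (including its seed).
    """
    rng = np.random.default_rng(config.seed)
    assignment = config.module_assignment
    radius = config.ar_spectral_radius

    # population-level epoch matrices: ordered drift toward random targets
    epochs = [_modular_matrix(rng, assignment, radius)]
    for _ in range(1, config.n_epochs):
        target = _modular_matrix(rng, assignment, radius)
        mixed = (1.0 - config.drift_rate) * epochs[-1] + config.drift_rate * target
        epochs.append(_rescale_radius(mixed, radius))

    bounds = np.linspace(0, config.n_timepoints, config.n_epochs + 1).astype(int)

    subjects: list[TimeSeriesData] = []
    subject_mats: list[list[np.ndarray]] = []
    for _ in range(config.n_subjects):
        sub_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
        if config.subject_sd > 0:
            pert = sub_rng.normal(0.0, config.subject_sd, (config.n_regions,) * 2)
            mats = [_rescale_radius(C + pert, radius) for C in epochs]
        else:
            mats = [C.copy() for C in epochs]
        x = sub_rng.normal(0.0, 1.0, config.n_regions)
        series = np.empty((config.n_regions, config.n_timepoints))
        for e, C in enumerate(mats):
            for t in range(bounds[e], bounds[e + 1]):
                x = C @ x
                if config.noise_sd > 0:
                    x = x + sub_rng.normal(0.0, config.noise_sd, config.n_regions)
                series[:, t] = x
        if not np.all(np.isfinite(series)):
            raise FloatingPointError("simulated series diverged")
        subjects.append(TimeSeriesData(series))
        subject_mats.append(mats)

    truth = GroundTruth(
        epoch_coefficient_matrices=epochs,
        epoch_boundaries=bounds,
        module_assignment=assignment.copy(),
        subject_matrices=subject_mats,
    )
    return subjects, truth


def generate_behavior_scores(
    features: np.ndarray,
    weights: np.ndarray,
    noise_sd: float,
    seed: int = 0,
) -> BehaviorScores:
    """Scores with a planted linear dependence on subject features.

    ``score_s = features_s . weights + N(0, noise_sd^2)``.  The returned
    ``theoretical_r`` is the population correlation between scores and the
    noiseless signal, ``sqrt(var(signal) / (var(signal) + noise_sd^2))``,
    using the empirical signal variance across subjects.
    """
    features = np.asarray(features, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if features.ndim != 2:
        raise ValueError("features must be subjects × features")
    if weights.shape != (features.shape[1],):
        raise ValueError("weights length must equal the feature count")
    if np.isnan(features).any():
        raise ValueError("features contain NaN")
    rng = np.random.default_rng(seed)
    signal = features @ weights
    scores = signal + rng.normal(0.0, noise_sd, features.shape[0])
    var_sig = float(np.var(signal))
    denom = var_sig + noise_sd**2
    theo_r = float(np.sqrt(var_sig / denom)) if denom > 0 else 0.0
    return BehaviorScores(scores, weights.copy(), noise_sd, theo_r)


def noise_sd_for_target_r(signal: np.ndarray, target_r: float) -> float:
    """Noise level giving a desired population signal-score correlation."""
    if not 0.0 < target_r <= 1.0:
        raise ValueError("target_r must lie in (0, 1]")
    sd = float(np.std(signal))
    return sd * np.sqrt(1.0 / target_r**2 - 1.0)


def sample_transition_endpoints(
    ts: TimeSeriesData,
    n_samples: int = 12,
    min_separation: int = 180,
    seed: int = 0,
) -> list[tuple[int, int]]:
    """Uniformly sample ordered frame pairs bounding state transitions.

    Each pair ``(start, end)`` satisfies ``end - start >= min_separation``
    (default three 60-frame windows).  The segment between the two frames
    is what the snapshot-switching energy experiment operates on.
    """
    T = ts.n_frames
    if min_separation >= T:
        raise ValueError(
            f"min_separation {min_separation} infeasible for {T} frames"
        )
    rng = np.random.default_rng(seed)
    pairs: list[tuple[int, int]] = []
    for _ in range(n_samples):
        start = int(rng.integers(0, T - min_separation))
        end = int(rng.integers(start + min_separation, T + 1))
        pairs.append((start, end))
    return pairs
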