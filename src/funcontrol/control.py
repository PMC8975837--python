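"""Linear control model on normalized connectivity.

Connectivity F is turned into the interaction matrix of the continuous
linear system  x'(t) = A x(t) + B u(t)  via a signed weighted Laplacian,

    L_ij = delta_ij * sum_k |F_ik| - F_ij,        A = -L / lambda_max(L),

with lambda_max the largest absolute eigenvalue of L.  The scaling puts
the spectrum of A (symmetric F) inside [-1, 0]; the zero mode that a
nonnegative F always produces makes A only marginally stable, so a small
diagonal shift is subtracted before any infinite-horizon computation.

From A we derive the regional control measures used as features:

* average controllability  psi_i = trace of the infinite-horizon Gramian
  with the single-region input matrix B_i,
* modal controllability    phi_i = sum_j (1 - lambda_j^2) v_ij^2,
* regional activation energy  eps_i = (1/2) e_i^T W(tau)^{-1} e_i,
  the minimum energy of the 0 -> e_i transition with full control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm, solve_continuous_lyapunov

from .connectivity import ConnectivityMatrix

__all__ = [
    "NormalizedInteraction",
    "ControllabilityProfile",
    "signed_laplacian",
    "laplacian_normalize",
    "control_matrix",
    "infinite_horizon_gramian",
    "finite_horizon_gramian",
    "average_controllability",
    "modal_controllability",
    "activation_energy",
    "controllability_profile",
    "dynamic_controllability",
]

#: default diagonal stabilization for marginally stable interaction matrices
DEFAULT_SHIFT = 1e-6
_MARGINAL_TOL = 1e-10
_COND_LIMIT = 1e12


@dataclass
class NormalizedInteraction:
    """Stabilized interaction matrix derived from one connectivity matrix.

    ``A_raw`` is the exact normalization -L/lambda_max; ``A`` is the matrix
    used downstream, equal to ``A_raw - stabilization_shift * I`` (the
    shift is 0 whenever A_raw is already strictly stable).
    """

    A: np.ndarray
    A_raw: np.ndarray
    L: np.ndarray
    lambda_max: float
    stabilization_shift: float
    source_kind: str

    @property
    def n_regions(self) -> int:
        return self.A.shape[0]


@dataclass
class ControllabilityProfile:
    """Per-region control measures for one interaction matrix (or an
    average over a snapshot sequence)."""

    average: np.ndarray
    modal: np.ndarray
    activation_energy: np.ndarray
    source_kind: str


def signed_laplacian(F: np.ndarray) -> np.ndarray:
    """Weighted signed Laplacian L_ij = delta_ij sum_k |F_ik| - F_ij."""
    F = np.asarray(F, dtype=float)
    L = -F.copy()
    L[np.diag_indices_from(L)] += np.sum(np.abs(F), axis=1)
    return L


def laplacian_normalize(
    F: ConnectivityMatrix | np.ndarray,
    stabilize: bool = True,
    shift: float = DEFAULT_SHIFT,
) -> NormalizedInteraction:
    """Normalize connectivity into a stable interaction matrix.

    Raises on an all-zero (degenerate) connectivity matrix.  When the
    normalized matrix is only marginally stable (largest real eigenvalue
    above ``-1e-10``) and ``stabilize`` is set, ``shift`` is subtracted
    from the diagonal and recorded.
    """
    if isinstance(F, ConnectivityMatrix):
        kind = F.kind
        mat = F.matrix
    else:
        kind = "unknown"
        mat = np.asarray(F, dtype=float)
    if not np.all(np.isfinite(mat)):
        raise ValueError("connectivity matrix contains non-finite values")
    L = signed_laplacian(mat)
    eigs = np.linalg.eigvals(L)
    lam_max = float(np.max(np.abs(eigs)))
    if lam_max <= 0:
        raise ValueError("degenerate connectivity: Laplacian has zero spectrum")
    A_raw = -L / lam_max
    applied = 0.0
    A = A_raw
    if stabilize:
        max_real = float(np.max(np.linalg.eigvals(A_raw).real))
        if max_real > -_MARGINAL_TOL:
            applied = shift
            A = A_raw - shift * np.eye(A_raw.shape[0])
            warnings.warn(
                f"interaction matrix marginally stable (max Re eig "
                f"{max_real:.2e}); applied diagonal shift {shift:g}",
                RuntimeWarning,
                stacklevel=2,
            )
    return NormalizedInteraction(A, A_raw, L, lam_max, applied, kind)


def control_matrix(n_regions: int, control_set: np.ndarray | list[int]) -> np.ndarray:
    """Input matrix B whose columns are identity columns of the control set."""
    control_set = np.asarray(control_set, dtype=int)
    if control_set.size == 0:
        raise ValueError("control set is empty")
    if len(np.unique(control_set)) != control_set.size:
        raise ValueError("control set has repeated regions")
    B = np.zeros((n_regions, control_set.size))
    B[control_set, np.arange(control_set.size)] = 1.0
    return B


def infinite_horizon_gramian(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Infinite-horizon controllability Gramian via the Lyapunov equation.

    Solves ``A W + W A^T + B B^T = 0``; requires a strictly stable
    (Hurwitz) A — normalize with stabilization first.
    """
    A = np.asarray(A, dtype=float)
    max_real = float(np.max(np.linalg.eigvals(A).real))
    if max_real > -_MARGINAL_TOL:
        raise ValueError(
            "A is not strictly stable; apply laplacian_normalize stabilization"
        )
    W = solve_continuous_lyapunov(A, -B @ B.T)
    return 0.5 * (W + W.T)


def finite_horizon_gramian(A: np.ndarray, B: np.ndarray, tau: float) -> np.ndarray:
    """Finite-horizon Gramian W(tau) = int_0^tau e^{At} B B^T e^{A^T t} dt.

    Computed with the augmented-matrix exponential construction: for
    ``H = [[-A, B B^T], [0, A^T]] * t`` the exponential's upper-right
    block G and lower-right block F satisfy ``W(t) = F^T G``.  Because
    the augmented matrix contains -A, whose exponential grows on long
    horizons for stable A, the construction is applied on a scaled
    sub-interval and extended by the doubling identity
    ``W(2t) = W(t) + e^{At} W(t) e^{A^T t}``.  Valid for any A
    (stability not required) and any tau >= 0.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if tau < 0:
        raise ValueError("horizon tau must be nonnegative")
    n = A.shape[0]
    if tau == 0:
        return np.zeros((n, n))
    # scale so the augmented exponential stays well-conditioned
    norm = np.linalg.norm(A, 2)
    n_double = max(0, int(np.ceil(np.log2(max(norm * tau, 1e-30))))) if norm * tau > 1 else 0
    t_small = tau / (2**n_double)
    H = np.zeros((2 * n, 2 * n))
    H[:n, :n] = -A
    H[:n, n:] = B @ B.T
    H[n:, n:] = A.T
    E = expm(H * t_small)
    W = E[n:, n:].T @ E[:n, n:]
    W = 0.5 * (W + W.T)
    Phi = expm(A * t_small)
    for _ in range(n_double):
        W = W + Phi @ W @ Phi.T
        W = 0.5 * (W + W.T)
        Phi = Phi @ Phi
    return W


def average_controllability(
    A: np.ndarray, regions: np.ndarray | list[int] | None = None
) -> np.ndarray:
    """Average controllability psi_i = Trace(W_i) per candidate controller.

    W_i is the infinite-horizon Gramian for the single-region input
    matrix B_i (i-th diagonal 1).  Returns one value per requested region
    (default: all regions).
    """
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    if regions is None:
        regions = np.arange(n)
    regions = np.asarray(regions, dtype=int)
    psi = np.empty(regions.size)
    for k, i in enumerate(regions):
        B = np.zeros((n, 1))
        B[i, 0] = 1.0
        psi[k] = float(np.trace(infinite_horizon_gramian(A, B)))
    return psi


def modal_controllability(A: np.ndarray) -> np.ndarray:
    """Modal controllability phi_i = sum_j (1 - lambda_j^2) v_ij^2.

    For an asymmetric A (the autoregression-derived case) eigenvalues may
    be complex; |lambda_j|^2 and |v_ij|^2 are used, with a warning, as the
    explicit extension of the real-spectrum formula.  Eigenvectors are
    normalized to unit Euclidean norm.
    """
    A = np.asarray(A, dtype=float)
    lam, V = np.linalg.eig(A)
    V = V / np.linalg.norm(V, axis=0, keepdims=True)
    if np.iscomplexobj(lam) and np.max(np.abs(lam.imag)) > 1e-12:
        warnings.warn(
            "complex eigenvalues: modal controllability uses |lambda|^2 "
            "and |v_ij|^2",
            RuntimeWarning,
            stacklevel=2,
        )
    weight = 1.0 - np.abs(lam) ** 2
    return np.abs(V) ** 2 @ weight


def activation_energy(A: np.ndarray, tau: float = 1.0) -> np.ndarray:
    """Minimum energy to activate each region from the zero state.

    With full control (B = I) and x0 = 0 the drift-corrected difference
    for the 0 -> e_i transition is e_i itself, so
    ``eps_i = (1/2) (W(tau)^{-1})_{ii}``.  The horizon defaults to one
    frame (TR unit).
    """
    if tau <= 0:
        raise ValueError("activation-energy horizon must be positive")
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    W = finite_horizon_gramian(A, np.eye(n), tau)
    Winv = _monitored_inverse(W)
    return 0.5 * np.diag(Winv).copy()


def controllability_profile(
    interaction: NormalizedInteraction, activation_tau: float = 1.0
) -> ControllabilityProfile:
    """All three regional control measures for one interaction matrix."""
    A = interaction.A
    return ControllabilityProfile(
        average=average_controllability(A),
        modal=modal_controllability(A),
        activation_energy=activation_energy(A, activation_tau),
        source_kind=interaction.source_kind,
    )


def dynamic_controllability(
    interactions: list[NormalizedInteraction], activation_tau: float = 1.0
) -> ControllabilityProfile:
    """Snapshot-sequence control measures: per-window profiles, averaged
    unweighted over the M windows."""
    if not interactions:
        raise ValueError("need at least one snapshot")
    profiles = []
    for inter in interactions:
        try:
            profiles.append(controllability_profile(inter, activation_tau))
        except (ValueError, np.linalg.LinAlgError) as exc:  # pragma: no cover
            warnings.warn(
                f"skipping degenerate snapshot: {exc}", RuntimeWarning, stacklevel=2
            )
    if not profiles:
        raise ValueError("no valid snapshot in the sequence")
    return ControllabilityProfile(
        average=np.mean([p.average for p in profiles], axis=0),
        modal=np.mean([p.modal for p in profiles], axis=0),
        activation_energy=np.mean([p.activation_energy for p in profiles], axis=0),
        source_kind="window_correlation",
    )


def _monitored_inverse(W: np.ndarray) -> np.ndarray:
    """Symmetric inverse with a pseudo-inverse fallback for bad conditioning."""
    cond = np.linalg.cond(W)
    if cond > _COND_LIMIT or not np.isfinite(cond):
        warnings.warn(
            f"Gramian condition number {cond:.2e}; using pseudo-inverse",
            RuntimeWarning,
            stacklevel=3,
        )
        return np.linalg.pinv(W, rcond=1e-12, hermitian=True)
    return np.linalg.inv(W)
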