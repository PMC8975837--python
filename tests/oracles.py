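"""Independent oracles used by the test suite.

Each oracle reaches its result by a computational path disjoint from the
library: Gramians by trapezoidal quadrature of the defining integral
(propagator accumulated by repeated multiplication, not expm-per-call of
the augmented matrix), minimum energies by a least-norm discretized
control problem, local efficiency by networkx Dijkstra shortest paths,
and average controllability by the eigen-expansion valid for symmetric
stable matrices.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
from scipy.linalg import expm


def gramian_quadrature(
    A: np.ndarray, B: np.ndarray, t_max: float, dt: float = 1e-3
) -> np.ndarray:
    """Composite-Simpson quadrature of int_0^t_max e^{At} BB^T e^{A^T t} dt.

    The integrand is evaluated on a uniform grid with the propagator
    accumulated by repeated multiplication (independent of the library's
    augmented-exponential route); Simpson weights give O(dt^4) accuracy.
    """
    n_steps = int(round(t_max / dt))
    if n_steps % 2:
        n_steps += 1
    dt = t_max / n_steps
    Phi_dt = expm(A * dt)
    Q = B @ B.T
    M = np.eye(A.shape[0])
    W = Q.copy()  # weight-1 endpoint at t=0
    for k in range(1, n_steps):
        M = Phi_dt @ M
        W += (4.0 if k % 2 else 2.0) * (M @ Q @ M.T)
    M = Phi_dt @ M
    W += M @ Q @ M.T
    return W * (dt / 3.0)


def least_norm_energy(
    mats: list[np.ndarray],
    durations: list[float],
    B: np.ndarray,
    x0: np.ndarray,
    xf: np.ndarray,
    dt: float = 1e-3,
) -> float:
    """Minimum int |u|^2 dt by zero-order-hold discretization.

    The system is discretized per snapshot with exact state propagators
    and first-order input maps; the least-norm discrete input solving the
    endpoint constraint has energy d^T G^{-1} d * dt with G the discrete
    reachability Gramian accumulated step by step.  Matches the
    continuous minimum energy to O(dt).  Note this is the classical
    energy, i.e. twice the half-quadratic-form convention.
    """
    n = mats[0].shape[0]
    G = np.zeros((n, n))
    drift = np.eye(n)
    for A, tau in zip(mats, durations):
        steps = int(round(tau / dt))
        Ad = expm(A * dt)
        Bd = dt * (np.eye(n) + 0.5 * dt * A) @ B
        Q = Bd @ Bd.T
        for _ in range(steps):
            G = Ad @ G @ Ad.T + Q
        drift = np.linalg.matrix_power(Ad, steps) @ drift
    d = xf - drift @ x0
    u_norm_sq = float(d @ np.linalg.solve(G, d))
    return u_norm_sq * dt


def local_efficiency_nx(F: np.ndarray) -> np.ndarray:
    """Cube-root weighted local efficiency via networkx Dijkstra paths."""
    W = np.abs(np.asarray(F, dtype=float))
    np.fill_diagonal(W, 0.0)
    n = W.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = np.nonzero(W[i] > 0)[0]
        k = nbrs.size
        if k < 2:
            continue
        G = nx.Graph()
        G.add_nodes_from(range(k))
        for a in range(k):
            for b in range(a + 1, k):
                w = W[nbrs[a], nbrs[b]]
                if w > 0:
                    G.add_edge(a, b, dist=1.0 / w)
        dists = dict(nx.all_pairs_dijkstra_path_length(G, weight="dist"))
        total = 0.0
        for a in range(k):
            for b in range(k):
                if a == b:
                    continue
                d = dists.get(a, {}).get(b, np.inf)
                if np.isfinite(d) and d > 0:
                    total += (W[i, nbrs[a]] * W[i, nbrs[b]] / d) ** (1.0 / 3.0)
        out[i] = total / (k * (k - 1))
    return out


def average_controllability_eigen(A: np.ndarray) -> np.ndarray:
    """psi_i = sum_j v_ij^2 / (-2 lambda_j) for symmetric stable A."""
    lam, V = np.linalg.eigh(A)
    return (V**2) @ (1.0 / (-2.0 * lam))


def random_stable(rng: np.random.Generator, n: int, margin: float = 0.5) -> np.ndarray:
    """Random dense matrix shifted to spectral abscissa -margin."""
    A = rng.normal(0.0, 1.0 / np.sqrt(n), (n, n))
    A -= np.eye(n) * (np.max(np.linalg.eigvals(A).real) + margin)
    return A
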