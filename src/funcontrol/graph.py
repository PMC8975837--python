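"""Regional graph-theoretic features of weighted connectivity.

All metrics operate on the absolute connectivity weights with the
diagonal excluded: signed functional connectivity has no canonical
distance interpretation, so negative edges enter through their
magnitude.  Local efficiency follows the cube-root weighted convention
common for brain graphs, with inverse-weight shortest-path distances
computed on each node's neighborhood subgraph.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.sparse.csgraph import shortest_path

__all__ = [
    "weighted_degree",
    "local_efficiency",
    "participation_coefficient",
]


def _abs_offdiag(F: np.ndarray) -> np.ndarray:
    W = np.abs(np.asarray(F, dtype=float))
    np.fill_diagonal(W, 0.0)
    return W


def weighted_degree(F: np.ndarray) -> np.ndarray:
    """Weighted degree (strength): k_i = sum_{j != i} |F_ij|."""
    return _abs_offdiag(F).sum(axis=1)


def local_efficiency(F: np.ndarray) -> np.ndarray:
    """Weighted local efficiency per node (cube-root convention).

    For node i with neighbors N(i), using absolute weights w and
    inverse-weight distances on the neighborhood subgraph,

        E_loc(i) = sum_{j,h in N(i), j != h} (w_ij w_ih / d_jh(N_i))^{1/3}
                   / (k_i (k_i - 1)),

    where k_i = |N(i)| and d_jh(N_i) is the shortest-path length between
    j and h within the subgraph induced by N(i).  Nodes with fewer than
    two neighbors score 0.  Asymmetric input is symmetrized with a
    warning.
    """
    F = np.asarray(F, dtype=float)
    if not np.allclose(F, F.T, atol=1e-12):
        warnings.warn(
            "asymmetric connectivity symmetrized as (F + F^T)/2 for "
            "local efficiency",
            RuntimeWarning,
            stacklevel=2,
        )
        F = 0.5 * (F + F.T)
    W = _abs_offdiag(F)
    n = W.shape[0]
    eff = np.zeros(n)
    for i in range(n):
        nbrs = np.nonzero(W[i] > 0)[0]
        k = nbrs.size
        if k < 2:
            continue
        sub = W[np.ix_(nbrs, nbrs)]
        with np.errstate(divide="ignore"):
            dist_w = np.where(sub > 0, 1.0 / sub, np.inf)
        np.fill_diagonal(dist_w, 0.0)
        d = shortest_path(dist_w, method="D", directed=False)
        with np.errstate(divide="ignore"):
            inv_d = np.where(np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
        w_i = W[i, nbrs]
        num = np.cbrt(np.outer(w_i, w_i) * inv_d)
        np.fill_diagonal(num, 0.0)
        eff[i] = num.sum() / (k * (k - 1))
    return eff


def participation_coefficient(
    F: np.ndarray, partition: np.ndarray | list[int]
) -> np.ndarray:
    """Participation coefficient P_i = 1 - sum_s (k_is / k_i)^2.

    k_is is node i's absolute strength into community s.  Isolated nodes
    (k_i = 0) score 0 by convention; the upper bound 1 - 1/n_communities
    is reached at a perfectly even spread.
    """
    W = _abs_offdiag(F)
    partition = np.asarray(partition, dtype=int)
    if partition.shape != (W.shape[0],):
        raise ValueError("partition must label every region")
    k = W.sum(axis=1)
    P = np.zeros(W.shape[0])
    nonzero = k > 0
    for s in np.unique(partition):
        k_s = W[:, partition == s].sum(axis=1)
        P[nonzero] += (k_s[nonzero] / k[nonzero]) ** 2
    P[nonzero] = 1.0 - P[nonzero]
    return P
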