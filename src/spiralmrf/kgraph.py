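"""Graph over the spiral readout points.

Spiral samples are not equally spaced, so a fixed-width 1D convolution along
the readout misrepresents the geometry.  The graph encodes actual pairwise
distances: a Gaussian-weighted adjacency

    A_ij = exp(-||v_i - v_j||^2 / dbar^2),

with ``dbar`` the mean distance over all unordered point pairs of one arm,
truncated per row to the K largest entries (the point itself always survives
since A_ii = 1 is the row maximum).  Graph convolution then aggregates with
the symmetrically normalized propagation matrix

    P = Dhat^{-1/2} Ahat Dhat^{-1/2},   Ahat = A_trunc + I,
    Dhat_ii = sum_j Ahat_ij.

The adjacency depends only on pairwise distances, so one graph serves every
golden-angle-rotated frame.

Row-wise truncation generally leaves A asymmetric; it is kept asymmetric by
default (a symmetrized variant is available via ``symmetrize=True``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.spatial.distance import pdist, squareform

__all__ = ["KSpaceGraph", "build_adjacency", "propagation_matrix"]


@dataclass
class KSpaceGraph:
    """kNN-truncated Gaussian adjacency over Q readout points."""

    coords: np.ndarray
    mean_pair_dist: float
    K: int
    adjacency: sp.csr_matrix
    symmetrized: bool = False
    _propagation: sp.csr_matrix | None = None

    @property
    def n_points(self) -> int:
        return self.coords.shape[0]

    @property
    def propagation(self) -> sp.csr_matrix:
        if self._propagation is None:
            self._propagation = propagation_matrix(self)
        return self._propagation


def build_adjacency(coords: np.ndarray, K: int, symmetrize: bool = False) -> KSpaceGraph:
    """Build the Gaussian kNN adjacency over readout-point coordinates.

    Per row, the K largest weights are retained (ties broken toward the
    smaller column index) and the rest set to zero.

    Parameters
    ----------
    coords:
        ``(Q, 2)`` point coordinates (cycles/FOV).
    K:
        Neighbors kept per row, including the point itself; ``1 <= K <= Q``.
    symmetrize:
        If True, replace the truncated adjacency by ``max(A, A.T)``.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords must have shape (Q, 2)")
    Q = coords.shape[0]
    if not (1 <= K <= Q):
        raise ValueError(f"K must satisfy 1 <= K <= Q={Q}, got {K}")

    dists = pdist(coords)  # condensed unordered pairs, self-pairs excluded
    dbar = float(dists.mean()) if dists.size else 1.0
    if dbar <= 0:
        raise ValueError("degenerate coordinates: mean pairwise distance is zero")
    dense = np.exp(-squareform(dists) ** 2 / dbar**2)  # A_ii = exp(0) = 1

    # Row-wise kNN truncation; ranking uses weights rounded to 10 decimals
    # so that near-ties (machine-precision distance differences, e.g. from
    # rotating the arm) resolve deterministically toward the smaller column
    # index.  Stored weights keep full precision.
    order = np.argsort(-np.round(dense, 10), axis=1, kind="stable")
    keep_cols = order[:, :K]
    rows = np.repeat(np.arange(Q), K)
    cols = keep_cols.ravel()
    vals = dense[rows, cols]
    adj = sp.csr_matrix((vals, (rows, cols)), shape=(Q, Q))
    if symmetrize:
        adj = adj.maximum(adj.T).tocsr()
    return KSpaceGraph(
        coords=coords, mean_pair_dist=dbar, K=int(K), adjacency=adj,
        symmetrized=bool(symmetrize),
    )


def propagation_matrix(graph: KSpaceGraph) -> sp.csr_matrix:
    """Normalized propagation matrix ``Dhat^{-1/2} (A + I) Dhat^{-1/2}``.

    The identity is added to the truncated adjacency even though the
    retained diagonal already equals 1, following the graph-convolution
    convention; the constant diagonal boost is absorbed by learned weights.
    """
    A = graph.adjacency
    Ahat = (A + sp.identity(A.shape[0], format="csr")).tocsr()
    deg = np.asarray(Ahat.sum(axis=1)).ravel()
    if np.any(deg <= 0):
        raise RuntimeError("zero row degree despite self-loop")  # unreachable
    dinv = sp.diags(1.0 / np.sqrt(deg))
    return (dinv @ Ahat @ dinv).tocsr()
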