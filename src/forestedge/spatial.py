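"""Spatial weights, Moran's I and Moran eigenvector bases.

The connectivity is a symmetrised k-nearest-neighbour graph on point
coordinates.  Moran eigenvectors are the eigenvectors of the doubly-centred
connectivity matrix ``M = C W C`` with ``C = I - 11'/n``; each eigenvector
is centred, they are mutually orthogonal, and the Moran's I of eigenvector
``v`` equals ``(n / S0) * lambda_v``, so sorting by eigenvalue sorts by
spatial smoothness.  Vectors in the null space of ``M`` (including the
constant) carry no spatial pattern and are dropped, which bounds the basis
size at ``n - 1``.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse
from sklearn.neighbors import NearestNeighbors

__all__ = ["knn_graph", "morans_i", "moran_permutation_test", "moran_eigenvectors"]


def knn_graph(coords: np.ndarray, k: int = 8) -> sparse.csr_matrix:
    """Symmetrised binary k-nearest-neighbour connectivity matrix.

    ``W[i, j] = 1`` if j is among i's k nearest neighbours or vice versa
    (max-symmetrisation keeps W symmetric, as the eigendecomposition
    requires).  Duplicate coordinates are legal as long as at least three
    distinct locations exist.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords must be an (n, 2) array")
    n = coords.shape[0]
    n_distinct = np.unique(coords, axis=0).shape[0]
    if n_distinct < 3:
        raise ValueError(
            f"need >= 3 distinct coordinates, got {n_distinct}"
        )
    k_eff = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(coords)
    graph = nn.kneighbors_graph(coords, mode="connectivity")
    graph = graph.tolil()
    graph.setdiag(0)
    graph = graph.tocsr()
    w = graph.maximum(graph.T)
    w.eliminate_zeros()
    if w.nnz == 0:
        raise ValueError("singular connectivity: graph has no edges")
    return w.tocsr()


def morans_i(x: np.ndarray, w: sparse.spmatrix) -> float:
    """Moran's I of ``x`` under connectivity ``w``.

    ``I = (n / S0) * z' W z / z' z`` with ``z`` the centred variable and
    ``S0`` the sum of all weights.  Returns NaN for a constant variable.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    z = x - x.mean()
    denom = float(z @ z)
    if denom == 0:
        return float("nan")
    s0 = float(w.sum())
    return float(n / s0 * (z @ (w @ z)) / denom)


def moran_permutation_test(
    x: np.ndarray,
    w: sparse.spmatrix,
    n_permutations: int = 199,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """One-sided (positive autocorrelation) permutation test of Moran's I.

    Returns ``(I_obs, p)`` with ``p = (1 + #{I_perm >= I_obs}) /
    (n_permutations + 1)``.  ``z'z`` and ``S0`` are permutation-invariant,
    so only the cross product is recomputed per shuffle.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    x = np.asarray(x, dtype=float)
    n = x.size
    z = x - x.mean()
    denom = float(z @ z)
    if denom == 0:
        return float("nan"), float("nan")
    s0 = float(w.sum())
    scale = n / s0 / denom
    i_obs = scale * float(z @ (w @ z))
    count = 0
    for _ in range(n_permutations):
        zp = rng.permutation(z)
        if scale * float(zp @ (w @ zp)) >= i_obs:
            count += 1
    return i_obs, (1 + count) / (n_permutations + 1)


def moran_eigenvectors(
    coords: np.ndarray,
    k: int = 8,
    w: sparse.spmatrix | None = None,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvector basis of the doubly-centred connectivity matrix.

    Returns ``(E, moran)``: columns of ``E`` are centred, mutually
    orthonormal eigenvectors sorted by descending Moran's I, and ``moran``
    the corresponding I values.  At most ``n - 1`` vectors are returned;
    null-space vectors (|eigenvalue| <= tol) are dropped.
    """
    if w is None:
        w = knn_graph(coords, k)
    n = w.shape[0]
    wd = w.toarray().astype(float)
    centered = wd - wd.mean(axis=0, keepdims=True)
    m = centered - centered.mean(axis=1, keepdims=True)
    m = (m + m.T) / 2.0  # guard symmetry against rounding
    eigval, eigvec = np.linalg.eigh(m)
    keep = np.abs(eigval) > tol
    eigval, eigvec = eigval[keep], eigvec[:, keep]
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    s0 = float(w.sum())
    moran = n / s0 * eigval
    return eigvec, moran
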