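"""Classical (Torgerson) multidimensional scaling.

Projects contig coverage profiles into a low-dimensional space in which
Euclidean distances approximate the original ones. For Euclidean input the
embedding is exact up to the target rank (and coincides with principal
coordinates), which is what makes the method testable against a direct
distance oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

# eigenvalues below this fraction of the leading one are treated as null
_RANK_RTOL = 1e-12


@dataclass
class Embedding:
    """MDS coordinates with their eigenvalue spectrum.

    ``rank_deficient`` is set when fewer than ``d`` meaningfully positive
    eigenvalues exist; the missing coordinates are zero columns.
    """

    coords: np.ndarray = field(repr=False)
    eigenvalues: np.ndarray
    rank_deficient: bool = False


def classical_mds(X: np.ndarray, d: int) -> Embedding:
    """Torgerson scaling of the rows of ``X`` into ``d`` dimensions.

    Squared Euclidean distances between rows are double-centred
    (B = -1/2 J D2 J); the top-``d`` eigenpairs of B give the coordinates
    (eigenvectors scaled by the square roots of their eigenvalues). Negative
    eigenvalues are clamped to zero; eigenvalues are reported descending.
    """
    X = np.asarray(X, dtype=float)
    if d < 1:
        raise ValueError("target dimension d must be >= 1")
    n = X.shape[0]
    if n < d + 1:
        raise ValueError(f"need at least d+1={d + 1} rows, got {n}")

    D2 = squareform(pdist(X, metric="sqeuclidean"))
    row_mean = D2.mean(axis=1, keepdims=True)
    B = -0.5 * (D2 - row_mean - row_mean.T + D2.mean())

    # top-d eigenpairs of the symmetric centred matrix
    w, v = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:d]
    w = w[order]
    v = v[:, order]

    positive = w > max(w[0], 0.0) * _RANK_RTOL if w.size else np.array([], bool)
    rank_deficient = bool((~positive).any())
    w_clamped = np.where(positive, w, 0.0)
    coords = v * np.sqrt(w_clamped)
    coords[:, ~positive] = 0.0
    return Embedding(coords=coords, eigenvalues=w_clamped, rank_deficient=rank_deficient)
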