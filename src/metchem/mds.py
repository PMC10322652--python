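"""Classical (Torgerson) multidimensional scaling.

Tanimoto dissimilarity matrices need not be Euclidean, so the double-centred
Gram matrix can have negative eigenvalues; those axes are truncated and only
strictly positive eigenvalues are retained, up to the requested dimension
(50 by default). The procedure is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegeneracyError, ParameterError
from .fingerprints import DissimilarityMatrix


@dataclass
class MdsCoordinates:
    """Metabolite coordinates from classical scaling.

    ``coords`` is n x k with axes ordered by descending eigenvalue;
    ``eigenvalues`` holds the k retained (strictly positive) values.
    """

    coords: np.ndarray
    eigenvalues: np.ndarray
    labels: list[str]

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def k(self) -> int:
        return self.coords.shape[1]


def classical_mds(d: np.ndarray, dims: int) -> tuple[np.ndarray, np.ndarray]:
    """Torgerson scaling of a square dissimilarity matrix.

    Returns (coords, eigenvalues) keeping min(dims, #positive eigenvalues)
    axes. Raises :class:`DegeneracyError` when no eigenvalue is positive
    (e.g. an all-zero matrix).
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ (d**2) @ J
    B = (B + B.T) / 2.0
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    tol = max(abs(w[0]), abs(w[-1]), 1.0) * 1e-12
    n_pos = int(np.sum(w > tol))
    if n_pos == 0:
        raise DegeneracyError("no positive eigenvalue: degenerate dissimilarity matrix")
    k = min(dims, n_pos)
    coords = V[:, :k] * np.sqrt(w[:k])
    # deterministic axis signs: largest-magnitude loading positive
    for j in range(k):
        i_max = int(np.argmax(np.abs(coords[:, j])))
        if coords[i_max, j] < 0:
            coords[:, j] = -coords[:, j]
    return coords, w[:k].copy()


def mds_embed(D: DissimilarityMatrix, dims: int = 50) -> MdsCoordinates:
    """Embed a Tanimoto dissimilarity matrix by classical scaling."""
    if dims < 1:
        raise ParameterError(f"dims must be >= 1, got {dims}")
    coords, eigenvalues = classical_mds(D.d, dims)
    return MdsCoordinates(coords, eigenvalues, list(D.labels))
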