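"""Accuracy-maximization ("KODAMA"-style) sharpening of the MDS space.

The procedure amplifies local cluster structure before the final 2D map.
Each cycle starts from a random partition of the points into a small number
of classes and relaxes it towards self-consistency under a k-nearest-
neighbour classifier: points are revisited in random order and take the
majority label of their k nearest neighbours, until the leave-one-out
cross-validated accuracy (the fraction of points whose label matches their
neighbourhood majority) stops increasing, or an iteration cap is hit. After
many cycles, the fraction of cycles in which two points end with the same
label forms a proximity matrix: near 1 inside a tight cluster, near
1/n_classes between unrelated points. The 2D "chemical distance" map is the
classical MDS embedding of ``1 - proximity``.

All randomness flows from one integer seed; per-cycle streams are derived
through a seed sequence, so results are reproducible from a single number.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .errors import DegeneracyError, InsufficientDataError, ParameterError
from .mds import MdsCoordinates, classical_mds


@dataclass
class ProximityMatrix:
    """Fraction of accuracy-maximization cycles placing two points together.

    Entries lie on the grid {0, 1/cycles, ..., 1}; the diagonal is 1.
    """

    p: np.ndarray
    cycles: int
    labels: list[str]

    def __post_init__(self):
        p = np.asarray(self.p, dtype=float)
        if not np.allclose(p, p.T):
            raise ValueError("proximity matrix must be symmetric")
        if p.min() < 0 or p.max() > 1 + 1e-12:
            raise ValueError("proximities must lie in [0, 1]")
        self.p = p


@dataclass
class Embedding2D:
    """Two-dimensional chemical-distance map; rows follow panel order."""

    coords: np.ndarray
    seed: int
    labels: list[str]

    @property
    def n(self) -> int:
        return self.coords.shape[0]


def _as_coords(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, MdsCoordinates):
        return np.asarray(X.coords, dtype=float), list(X.labels)
    X = np.asarray(X, dtype=float)
    return X, [str(i) for i in range(X.shape[0])]


def accuracy_maximization(
    X,
    cycles: int = 20,
    seed: int = 0,
    n_classes: int = 5,
    max_iter: int = 20,
    knn: int = 5,
) -> ProximityMatrix:
    """Run the cyclic label-relaxation and accumulate the proximity matrix.

    Parameters
    ----------
    X:
        :class:`MdsCoordinates` or an (n, k) array.
    cycles:
        Number of independent random restarts averaged into the proximity.
    n_classes:
        Number of classes in the random initial partition of each cycle.
    max_iter:
        Cap on relaxation sweeps per cycle.
    knn:
        Neighbourhood size of the majority-vote classifier (capped at n-1).
    """
    coords, labels_names = _as_coords(X)
    n = coords.shape[0]
    if n < 4:
        raise InsufficientDataError(f"accuracy maximization needs n >= 4, got {n}")
    if cycles < 1:
        raise ParameterError(f"cycles must be >= 1, got {cycles}")
    if n_classes < 2 or max_iter < 1 or knn < 1:
        raise ParameterError("n_classes >= 2, max_iter >= 1 and knn >= 1 required")

    dist = cdist(coords, coords)
    np.fill_diagonal(dist, np.inf)
    k = min(knn, n - 1)
    # stable argsort keeps tie-breaking deterministic
    nbrs = np.argsort(dist, axis=1, kind="stable")[:, :k]

    same = np.zeros((n, n), dtype=np.int64)
    children = np.random.SeedSequence(seed).spawn(cycles)
    for child in children:
        rng = np.random.default_rng(child)
        labels = rng.integers(0, n_classes, n)
        best = -1.0
        for _ in range(max_iter):
            for i in rng.permutation(n):
                votes = labels[nbrs[i]]
                vals, counts = np.unique(votes, return_counts=True)
                labels[i] = vals[np.argmax(counts)]
            pred = np.empty(n, dtype=np.int64)
            for i in range(n):
                vals, counts = np.unique(labels[nbrs[i]], return_counts=True)
                pred[i] = vals[np.argmax(counts)]
            acc = float(np.mean(pred == labels))
            if acc <= best:
                break
            best = acc
        same += labels[:, None] == labels[None, :]
    p = same / cycles
    np.fill_diagonal(p, 1.0)
    return ProximityMatrix(p, cycles, labels_names)


def kodama_embed(
    X,
    cycles: int = 20,
    seed: int = 0,
    n_classes: int = 5,
    max_iter: int = 20,
    knn: int = 5,
) -> Embedding2D:
    """Two-dimensional chemical-distance map of the metabolites.

    Runs :func:`accuracy_maximization`, converts the proximity matrix to a
    dissimilarity ``1 - p`` and embeds it in two dimensions by classical MDS.
    A fully degenerate proximity (all points always together) maps every
    point to the origin.
    """
    prox = accuracy_maximization(
        X, cycles=cycles, seed=seed, n_classes=n_classes, max_iter=max_iter, knn=knn
    )
    d = 1.0 - prox.p
    np.fill_diagonal(d, 0.0)
    n = d.shape[0]
    try:
        coords, _ = classical_mds(d, 2)
    except DegeneracyError:
        coords = np.zeros((n, 2))
    if coords.shape[1] < 2:
        coords = np.hstack([coords, np.zeros((n, 2 - coords.shape[1]))])
    return Embedding2D(coords, int(seed), prox.labels)
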