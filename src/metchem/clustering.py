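"""Chemical-class detection on the 2D embedding.

The full structural chain (fingerprints -> Tanimoto -> MDS -> accuracy-
maximization 2D embedding) is repeated several times with derived seeds
(the MDS stage is deterministic, so repeats re-randomize only the
accuracy-maximization stage). For each repeat a Ward dendrogram is cut at
every k in [2, kmax] and Rousseeuw's silhouette index recorded; the mean
profile across repeats selects k* (ties break towards the smallest k), and
final labels come from consensus clustering: average linkage on
1 - co-association across repeats, cut at k*.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, linkage, to_tree
from scipy.spatial.distance import cdist, squareform

from .errors import InsufficientDataError, ParameterError, UndefinedIndexError
from .fingerprints import FingerprintScheme, dissimilarity_matrix
from .kodama import kodama_embed
from .mds import mds_embed
from .panel import MetabolitePanel

logger = logging.getLogger(__name__)

DEFAULT_KMAX = 30


@dataclass
class Dendrogram:
    """A scipy linkage matrix with its leaf labels."""

    linkage: np.ndarray
    labels: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def to_newick(self) -> str:
        """Export the merge tree in Newick format with height-difference
        branch lengths."""
        root = to_tree(self.linkage)

        def rec(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                name = self.labels[node.id].replace(" ", "_").replace(",", "_")
                return f"{name}:{length:.10g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:.10g}"

        left = rec(root.left, root.dist)
        right = rec(root.right, root.dist)
        return f"({left},{right});"


@dataclass
class SilhouetteProfile:
    """Mean silhouette per candidate k, with the per-repeat values."""

    ks: list[int]
    mean: np.ndarray
    per_repeat: np.ndarray  # repeats x len(ks)

    def to_frame(self) -> pd.DataFrame:
        sd = self.per_repeat.std(axis=0, ddof=1) if self.per_repeat.shape[0] > 1 \
            else np.zeros(len(self.ks))
        return pd.DataFrame({"k": self.ks, "mean_silhouette": self.mean,
                             "sd_silhouette": sd})


@dataclass
class ClusterAssignment:
    """Final chemical-class labels with the evidence behind them."""

    labels: pd.Series  # name -> cluster id in 1..k_star
    k_star: int
    profile: SilhouetteProfile
    coassociation: np.ndarray = field(repr=False)
    mean_distance: np.ndarray = field(repr=False)  # repeat-averaged 2D distances
    names: list[str] = field(default_factory=list)

    def members(self, cluster_id: int) -> list[str]:
        return list(self.labels.index[self.labels == cluster_id])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"name": self.labels.index, "cluster": self.labels.values})


def silhouette_index(coords, labels) -> float:
    """Mean Rousseeuw silhouette ``(b - a) / max(a, b)`` over all points.

    ``a`` is the mean distance to the point's own cluster (excluding itself)
    and ``b`` the smallest mean distance to any other cluster. Points in
    singleton clusters contribute 0.
    """
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise UndefinedIndexError("silhouette undefined for a single cluster")
    d = cdist(coords, coords)
    s = np.zeros(len(labels))
    masks = {c: labels == c for c in uniq}
    for i in range(len(labels)):
        own = masks[labels[i]]
        n_own = own.sum()
        if n_own == 1:
            continue  # singleton contributes 0
        a = d[i, own].sum() / (n_own - 1)
        b = min(d[i, masks[c]].mean() for c in uniq if c != labels[i])
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(s.mean())


def _repeat_seed(master_seed: int, repeat: int) -> int:
    ss = np.random.SeedSequence(master_seed, spawn_key=(repeat,))
    return int(ss.generate_state(1)[0] % (2**31))


def detect_clusters(
    panel: MetabolitePanel,
    repeats: int = 10,
    kmax: int | None = None,
    seed: int = 0,
    scheme: FingerprintScheme = FingerprintScheme(),
    mds_dims: int = 50,
    cycles: int = 20,
    n_classes: int = 5,
    knn: int = 5,
) -> ClusterAssignment:
    """Identify chemical classes on the panel's structural 2D embedding.

    ``kmax=None`` (default) means ``min(30, n - 1)``; an explicit kmax must
    satisfy ``2 <= kmax < n``.
    """
    valid = panel.valid_names
    n = len(valid)
    if n < 4:
        raise InsufficientDataError(f"need >= 4 valid metabolites, got {n}")
    if repeats < 1:
        raise ParameterError("repeats must be >= 1")
    if kmax is None:
        kmax = min(DEFAULT_KMAX, n - 1)
    if kmax >= n:
        raise ParameterError(f"kmax ({kmax}) must be smaller than n ({n})")
    if kmax < 2:
        raise ParameterError("kmax must be >= 2")

    D = dissimilarity_matrix(panel, scheme)
    X = mds_embed(D, mds_dims)

    ks = list(range(2, kmax + 1))
    per_repeat = np.zeros((repeats, len(ks)))
    labels_by_repeat: list[dict[int, np.ndarray]] = []
    dist_sum = np.zeros((n, n))
    for r in range(repeats):
        emb = kodama_embed(X, cycles=cycles, seed=_repeat_seed(seed, r),
                           n_classes=n_classes, knn=knn)
        dist_sum += cdist(emb.coords, emb.coords)
        Z = linkage(emb.coords, method="ward")
        cuts = {}
        for j, k in enumerate(ks):
            lab = cut_tree(Z, n_clusters=k).ravel()
            cuts[k] = lab
            if len(np.unique(lab)) < 2:
                per_repeat[r, j] = np.nan
            else:
                per_repeat[r, j] = silhouette_index(emb.coords, lab)
        labels_by_repeat.append(cuts)

    mean_sil = np.nanmean(per_repeat, axis=0)
    k_star = ks[int(np.argmax(mean_sil))]  # argmax returns first max -> smallest k

    coassoc = np.zeros((n, n))
    for cuts in labels_by_repeat:
        lab = cuts[k_star]
        coassoc += lab[:, None] == lab[None, :]
    coassoc /= repeats

    Zc = linkage(squareform(1.0 - coassoc, checks=False), method="average")
    final = cut_tree(Zc, n_clusters=k_star).ravel() + 1
    profile = SilhouetteProfile(ks, mean_sil, per_repeat)
    logger.info("selected k*=%d (mean silhouette %.3f)", k_star,
                float(mean_sil.max()))
    return ClusterAssignment(
        labels=pd.Series(final, index=valid, name="cluster"),
        k_star=k_star,
        profile=profile,
        coassociation=coassoc,
        mean_distance=dist_sum / repeats,
        names=list(valid),
    )


def dendrogram_from_distance(dist: np.ndarray, labels: list[str]) -> Dendrogram:
    """Ward dendrogram from a square distance matrix."""
    if len(labels) < 2:
        raise InsufficientDataError(f"need >= 2 leaves, got {len(labels)}")
    Z = linkage(squareform(np.asarray(dist, dtype=float), checks=False),
                method="ward")
    return Dendrogram(Z, list(labels))


def cluster_dendrogram(assignment: ClusterAssignment, cluster_id: int) -> Dendrogram:
    """Ward dendrogram of one chemical class, built on the repeat-averaged
    embedding distances (stable across the stochastic repeats)."""
    members = assignment.members(cluster_id)
    if len(members) < 2:
        raise InsufficientDataError(
            f"cluster {cluster_id} has {len(members)} member(s); need >= 2"
        )
    idx = [assignment.names.index(m) for m in members]
    sub = assignment.mean_distance[np.ix_(idx, idx)]
    return dendrogram_from_distance(sub, members)
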