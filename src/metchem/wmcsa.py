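"""Weighted Metabolite Chemical Similarity Analysis (WMCSA).

Within a selected chemical class, every branch of the structural dendrogram
whose leaf set is large enough is a candidate *module* (nested and
overlapping modules are all kept). Each module is summarized by its *eigen
metabolite*: the first principal component of the members' standardized
concentration profiles, the metabolite analogue of WGCNA's eigengene.
Modules are then screened for group differences with a two-sided
Mann-Whitney U test (Welch's t selectable) and Benjamini-Hochberg control
across modules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import to_tree
from scipy.stats import mannwhitneyu, ttest_ind
from statsmodels.stats.multitest import multipletests

from .clustering import Dendrogram
from .errors import (
    ContrastError,
    DegeneracyError,
    InsufficientDataError,
    ParameterError,
)
from .panel import ConcentrationMatrix

logger = logging.getLogger(__name__)


@dataclass
class ModuleSet:
    """Candidate modules: module id -> member names, ids assigned in
    depth-first order from the dendrogram root (so id 1, when present, is the
    whole tree). ``parent`` maps a module to its nearest enclosing module."""

    modules: dict[int, frozenset[str]]
    parent: dict[int, int | None] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.modules)

    def __iter__(self):
        return iter(self.modules.items())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"module_id": mid, "name": name}
            for mid in sorted(self.modules)
            for name in sorted(self.modules[mid])
        ]
        return pd.DataFrame(rows, columns=["module_id", "name"])


@dataclass
class EigenMetaboliteMatrix:
    """Module x sample eigen-metabolite scores with per-module diagnostics."""

    scores: pd.DataFrame  # index module_id, columns sample_ids
    variance_explained: pd.Series
    member_correlations: pd.Series  # mean correlation of members with the score

    @property
    def module_ids(self) -> list[int]:
        return list(self.scores.index)

    def to_frame(self) -> pd.DataFrame:
        out = self.scores.copy()
        out.insert(0, "variance_explained", self.variance_explained)
        out.insert(1, "mean_member_correlation", self.member_correlations)
        out.index.name = "module_id"
        return out.reset_index()


def all_branches(tree: Dendrogram, min_size: int = 3) -> ModuleSet:
    """Enumerate every dendrogram branch with >= min_size leaves as a module.

    One candidate module per internal node, numbered by depth-first
    (pre-order) traversal from the root. ``min_size`` below 2 is rejected;
    ``min_size`` above the leaf count yields an empty set with a warning.
    """
    if min_size < 2:
        raise ParameterError(f"min_size must be >= 2, got {min_size}")
    n = tree.n_leaves
    if min_size > n:
        logger.warning("min_size %d exceeds leaf count %d: empty module set",
                       min_size, n)
        return ModuleSet({}, {})
    root = to_tree(tree.linkage)
    modules: dict[int, frozenset[str]] = {}
    parent: dict[int, int | None] = {}
    counter = 0

    def visit(node, enclosing: int | None):
        nonlocal counter
        if node.is_leaf():
            return
        leaves = frozenset(tree.labels[i] for i in node.pre_order(lambda x: x.id))
        mid = enclosing
        if len(leaves) >= min_size:
            counter += 1
            mid = counter
            modules[mid] = leaves
            parent[mid] = enclosing
        visit(node.left, mid)
        visit(node.right, mid)

    visit(root, None)
    return ModuleSet(modules, parent)


def eigen_metabolite(
    conc: ConcentrationMatrix, module
) -> tuple[pd.Series, float, float]:
    """Eigen-metabolite of one module.

    Member columns are standardized to zero mean and unit variance, and the
    first principal component's sample scores are returned with the variance
    fraction it explains. The sign is fixed so that the mean correlation
    between the score and the member profiles is non-negative.

    Returns ``(scores, variance_explained, mean_member_correlation)``.
    Constant member columns are dropped with a warning; a module left with
    fewer than two members is degenerate.
    """
    members = sorted(module)
    missing = [m for m in members if m not in conc.values.columns]
    if missing:
        raise ParameterError(f"module members missing from concentrations: {missing}")
    if conc.n_samples < 3:
        raise InsufficientDataError("eigen-metabolite needs >= 3 samples")
    X = conc.values[members].to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = [m for m, k in zip(members, keep) if not k]
        logger.warning("dropping constant member(s) %s", dropped)
        members = [m for m, k in zip(members, keep) if k]
        X, sd = X[:, keep], sd[keep]
    if len(members) < 2:
        raise DegeneracyError("module collapsed below 2 usable members")
    Xs = (X - X.mean(axis=0)) / sd
    U, S, _ = np.linalg.svd(Xs, full_matrices=False)
    scores = U[:, 0] * S[0]
    variance_explained = float(S[0] ** 2 / np.sum(S**2))
    with np.errstate(invalid="ignore"):
        corrs = np.array(
            [np.corrcoef(scores, Xs[:, j])[0, 1] for j in range(Xs.shape[1])]
        )
    mean_corr = float(np.nanmean(corrs))
    if mean_corr < 0:
        scores, mean_corr = -scores, -mean_corr
    return (
        pd.Series(scores, index=conc.values.index, name="eigen_metabolite"),
        variance_explained,
        mean_corr,
    )


def wmcsa_summarize(
    conc: ConcentrationMatrix, modules: ModuleSet
) -> EigenMetaboliteMatrix:
    """Eigen-metabolite summary of every module in the set.

    Nested modules that share members are summarized independently (no
    orthogonalization). Degenerate modules are dropped with a warning; an
    entirely degenerate set is an error.
    """
    rows, ve, mc = {}, {}, {}
    for mid, members in sorted(modules.modules.items()):
        try:
            scores, v, c = eigen_metabolite(conc, members)
        except (DegeneracyError, InsufficientDataError) as exc:
            logger.warning("dropping module %d: %s", mid, exc)
            continue
        rows[mid], ve[mid], mc[mid] = scores, v, c
    if not rows:
        raise InsufficientDataError("all modules degenerate: empty WMCSA result")
    scores = pd.DataFrame(rows).T
    scores.index.name = "module_id"
    return EigenMetaboliteMatrix(
        scores,
        pd.Series(ve, name="variance_explained"),
        pd.Series(mc, name="mean_member_correlation"),
    )


def differential_modules(
    E: EigenMetaboliteMatrix,
    groups: pd.Series,
    contrast: tuple[str, str],
    method: str = "mannwhitney",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Test every module's eigen-metabolite for a two-group difference.

    ``contrast`` names the two group levels (first vs second). The default
    test is the two-sided Mann-Whitney U (robust at the small per-group n
    typical of metabolomics designs); ``method="welch"`` uses Welch's t.
    P-values are Benjamini-Hochberg adjusted across modules.

    Returns a DataFrame with columns module_id, statistic, direction,
    p_value, p_adjusted, significant.
    """
    level_a, level_b = contrast
    groups = groups.reindex(E.scores.columns)
    for level in contrast:
        count = int((groups == level).sum())
        if count == 0:
            raise ContrastError(f"contrast level {level!r} absent from groups")
        if count < 3:
            raise ContrastError(f"contrast level {level!r} has {count} sample(s); need >= 3")
    mask_a = (groups == level_a).to_numpy()
    mask_b = (groups == level_b).to_numpy()

    stats, pvals, directions = [], [], []
    for mid in E.module_ids:
        x = E.scores.loc[mid].to_numpy(dtype=float)[mask_a]
        y = E.scores.loc[mid].to_numpy(dtype=float)[mask_b]
        pooled = np.concatenate([x, y])
        if np.all(pooled == pooled[0]):
            # no variation at all: mid-rank U, no evidence
            stats.append(len(x) * len(y) / 2.0)
            pvals.append(1.0)
            directions.append("none")
            continue
        if method == "mannwhitney":
            res = mannwhitneyu(x, y, alternative="two-sided")
        elif method == "welch":
            res = ttest_ind(x, y, equal_var=False)
        else:
            raise ParameterError(f"unknown test method {method!r}")
        stats.append(float(res.statistic))
        pvals.append(float(min(1.0, res.pvalue)))
        diff = np.median(x) - np.median(y)
        directions.append("up" if diff > 0 else ("down" if diff < 0 else "none"))
    p_adj = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "module_id": E.module_ids,
            "statistic": stats,
            "direction": directions,
            "p_value": pvals,
            "p_adjusted": p_adj,
            "significant": p_adj < alpha,
        }
    )
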