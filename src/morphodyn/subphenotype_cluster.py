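"""Sub-phenotype discovery: Lloyd k-means plus homogeneity-constrained k.

The clustering objective is the within-cluster sum of squares (WCSS); the
algorithm is plain Lloyd iteration from k randomly chosen data points, with
multi-restart.  Cluster quality against known sample identity is measured by
the entropy-based homogeneity score

    homogeneity = 1 - H(A | C) / H(A),

which is 1 when every cluster contains a single true class and 0 when the
clustering carries no class information, together with per-cluster purity
(majority-class fraction).  The number of sub-phenotypes is chosen by
maximizing global homogeneity subject to every cluster being > 95% pure.

k-means is implemented here (not delegated) because the iteration scheme,
empty-cluster repair and restart policy are part of the tested contract;
scikit-learn's implementation serves as an independent cross-check in the
test suite only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ClusterResult",
    "SelectKResult",
    "kmeans",
    "contingency",
    "homogeneity",
    "per_cluster_purity",
    "select_k",
    "prepare_cell_vectors",
]


@dataclass
class ClusterResult:
    assignments: np.ndarray
    centroids: np.ndarray
    k: int
    wcss: float
    n_iter: int
    converged: bool
    wcss_history: np.ndarray = field(repr=False, default=None)


def _lloyd_core(
    X: np.ndarray, centroids: np.ndarray, max_iter: int, tol: float
) -> ClusterResult:
    """Lloyd iteration from given starting means to an assignment fixed point.

    Assignment ties break toward the lowest cluster index; an empty cluster is
    reseeded at the point farthest from its assigned centroid; WCSS is
    asserted non-increasing across iterations (after the repair step, which is
    itself WCSS-decreasing).
    """
    k = len(centroids)
    n = len(X)
    centroids = centroids.astype(float).copy()
    prev_assign = None
    history: list[float] = []
    converged = False
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        assign = d2.argmin(axis=1)
        for c in range(k):
            if not (assign == c).any():
                far = int(d2[np.arange(n), assign].argmax())
                centroids[c] = X[far]
                assign[far] = c
                d2[:, c] = ((X - centroids[c]) ** 2).sum(axis=1)
        wcss = float(((X - centroids[assign]) ** 2).sum())
        if history and wcss > history[-1] + 1e-9:
            raise AssertionError("WCSS increased across a Lloyd iteration")
        history.append(wcss)
        if prev_assign is not None and np.array_equal(assign, prev_assign):
            converged = True
            break
        if len(history) >= 2 and history[-2] - history[-1] < tol:
            converged = True
            break
        prev_assign = assign
        for c in range(k):
            centroids[c] = X[assign == c].mean(axis=0)
    for c in range(k):
        members = X[assign == c]
        if len(members):
            centroids[c] = members.mean(axis=0)
    wcss = float(((X - centroids[assign]) ** 2).sum())
    return ClusterResult(
        assignments=assign,
        centroids=centroids,
        k=k,
        wcss=wcss,
        n_iter=len(history),
        converged=converged,
        wcss_history=np.asarray(history),
    )


def kmeans(
    X: np.ndarray,
    k: int,
    rng: np.random.Generator,
    n_init: int = 10,
    max_iter: int = 300,
    tol: float = 1e-6,
    init: str = "random",
) -> ClusterResult:
    """Best-of-``n_init`` Lloyd k-means by WCSS.

    Initialization picks k distinct data points at random ("k random points,
    called means"); ``init="k-means++"`` uses D^2 seeding instead.  Assignment
    is to the nearest mean by squared Euclidean distance; empty clusters are
    reseeded at the point farthest from its assigned centroid.  WCSS is
    asserted non-increasing over iterations.
    """
    X = np.asarray(X, float)
    if k > len(np.unique(X, axis=0)):
        raise ValueError(f"k={k} exceeds the number of distinct points")
    best = None
    for _ in range(n_init):
        if init == "k-means++":
            seeds = _kmeanspp_seeds(X, k, rng)
        else:
            seeds = X[rng.choice(len(X), size=k, replace=False)]
        result = _lloyd_core(X, seeds, max_iter, tol)
        if best is None or result.wcss < best.wcss:
            best = result
    return best


def _kmeanspp_seeds(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = len(X)
    centroids = [X[rng.integers(n)]]
    for _ in range(1, k):
        d2 = np.min(
            ((X[:, None, :] - np.asarray(centroids)[None, :, :]) ** 2).sum(axis=2),
            axis=1,
        )
        p = d2 / d2.sum() if d2.sum() > 0 else np.full(n, 1.0 / n)
        centroids.append(X[rng.choice(n, p=p)])
    return np.asarray(centroids)


# ---------------------------------------------------------------------------
# evaluation against known identity


def contingency(truth_labels, cluster_labels) -> pd.DataFrame:
    """Classes x clusters joint-count table."""
    truth_labels = np.asarray(truth_labels)
    cluster_labels = np.asarray(cluster_labels)
    if truth_labels.shape != cluster_labels.shape:
        raise ValueError("label vectors must have equal length")
    return pd.crosstab(pd.Series(truth_labels, name="class"),
                       pd.Series(cluster_labels, name="cluster"))


def homogeneity(truth_labels, cluster_labels, mode: str = "conditional") -> float:
    """1 - E(A|C)/E(A): 1 iff every cluster holds a single class.

    ``mode="conditional"`` (default) uses the cluster-size denominator
    n_mk / c_k inside the log — the standard conditional entropy H(A|C).
    ``mode="as_printed"`` divides by the class size a_m instead, exposed for
    comparison only (that form scores a single all-points cluster as 1).
    Natural logs; the base cancels in the ratio.  E(A) = 0 (a single true
    class) yields 1 by convention.
    """
    ct = contingency(truth_labels, cluster_labels).to_numpy(float)
    N = ct.sum()
    a_m = ct.sum(axis=1)
    c_k = ct.sum(axis=0)
    p_class = a_m / N
    ea = -np.sum(p_class[p_class > 0] * np.log(p_class[p_class > 0]))
    if ea == 0.0:
        return 1.0
    denom = a_m[:, None] if mode == "as_printed" else c_k[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(denom > 0, ct / denom, 0.0)
        logfrac = np.zeros_like(frac)
        np.log(frac, out=logfrac, where=frac > 0)
        terms = np.where(ct > 0, ct / N * logfrac, 0.0)
    eac = -terms.sum()
    return float(1.0 - eac / ea)


def per_cluster_purity(truth_labels, cluster_labels) -> np.ndarray:
    """max_m n_mk / c_k per (non-empty) cluster, in cluster-id order."""
    ct = contingency(truth_labels, cluster_labels).to_numpy(float)
    sizes = ct.sum(axis=0)
    if (sizes == 0).any():
        warnings.warn("empty clusters excluded from purity")
    keep = sizes > 0
    return ct[:, keep].max(axis=0) / sizes[keep]


# ---------------------------------------------------------------------------
# constrained choice of k


@dataclass
class SelectKResult:
    result: ClusterResult
    k: int
    homogeneity: float
    min_purity: float
    purities: np.ndarray
    constraint_met: bool
    evaluations: pd.DataFrame = field(repr=False, default=None)


def select_k(
    X: np.ndarray,
    truth_labels,
    k_range=range(2, 16),
    purity_threshold: float = 0.95,
    rng: np.random.Generator | None = None,
    n_init: int = 10,
    init: str = "random",
) -> SelectKResult:
    """Homogeneity-constrained choice of the number of sub-phenotypes.

    Runs k-means for each k; among the k whose minimum per-cluster purity
    exceeds ``purity_threshold``, returns the clustering maximizing global
    homogeneity (ties -> smallest k).  When no k satisfies the constraint the
    global-homogeneity argmax is returned flagged ``constraint_met=False``.
    """
    k_range = list(k_range)
    if not k_range:
        raise ValueError("empty k_range")
    if rng is None:
        rng = np.random.default_rng()
    truth_labels = np.asarray(truth_labels)

    rows, results = [], {}
    for k in k_range:
        res = kmeans(X, k, rng, n_init=n_init, init=init)
        h = homogeneity(truth_labels, res.assignments)
        pur = per_cluster_purity(truth_labels, res.assignments)
        results[k] = (res, h, pur)
        rows.append(
            {"k": k, "wcss": res.wcss, "homogeneity": h, "min_purity": pur.min()}
        )
    evals = pd.DataFrame(rows)

    ok = evals[evals["min_purity"] > purity_threshold]
    pool = ok if not ok.empty else evals
    # max homogeneity, ties to the smallest k (stable sort, k ascending)
    best_row = pool.sort_values(["homogeneity", "k"], ascending=[False, True]).iloc[0]
    k_sel = int(best_row["k"])
    res, h, pur = results[k_sel]
    return SelectKResult(
        result=res,
        k=k_sel,
        homogeneity=h,
        min_purity=float(pur.min()),
        purities=pur,
        constraint_met=not ok.empty,
        evaluations=evals,
    )


# ---------------------------------------------------------------------------
# bridging from feature tables


def prepare_cell_vectors(
    table: pd.DataFrame,
    n_components: int = 14,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell mean feature vectors, standardized and projected to
    ``n_components`` principal components (the same space the classifier
    uses).  Returns (X, cell_ids)."""
    from .phenotype_classify import fit_preprocessor

    feature_cols = [c for c in table.columns if c not in ("cell_id", "time_min")]
    means = table.groupby("cell_id")[feature_cols].mean()
    pre = fit_preprocessor(means.to_numpy(), n_components)
    return pre.transform(means.to_numpy()), means.index.to_numpy()
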