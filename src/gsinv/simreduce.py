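"""Sample-similarity analyses: PCA embedding with between-condition distances,
neighbor-joining sample trees, and hierarchical clustering with a separation
score.

PCA treats samples as observations and genes as features; features are
centered (no unit-variance scaling) and, by default, values are log2(x+1)
transformed first. Between-condition Euclidean distances are measured in the
2-D embedding. Neighbor joining is the classical agglomerative algorithm
(Q-matrix joins from a star topology) and is exact on additive distance
matrices; hierarchical clustering uses average linkage on the same distance
matrix, and separation is scored as the adjusted Rand index of the 2-cluster
cut against the condition labels.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, pdist, squareform
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score
import networkx as nx

from .dataio import ExpressionMatrix, GeneSet, NORMAL, TUMOR
from .trees import SampleTree

log = logging.getLogger(__name__)


@dataclass
class Embedding:
    sample_ids: list[str]
    coordinates: np.ndarray  # samples x 2
    explained_variance: tuple[float, float]


def _feature_matrix(m: ExpressionMatrix, subset, log_transform: bool) -> np.ndarray:
    sub = m if subset is None else m.subset(subset)
    X = sub.values.T  # samples x genes
    if log_transform:
        X = np.log2(X + 1.0)
    return X


def pca_embed(m: ExpressionMatrix, subset: GeneSet | None = None,
              log_transform: bool = True) -> Embedding:
    """Top-2 principal-component scores of the samples.

    Genes of the subset are the (centered) features. If the data admit fewer
    than two components the missing coordinates/variances are zero.
    """
    if m.n_samples < 3:
        raise ValueError("PCA embedding needs at least 3 samples")
    X = _feature_matrix(m, subset, log_transform)
    nc = int(min(2, X.shape[0], X.shape[1]))
    pca = PCA(n_components=nc)
    scores = pca.fit_transform(X)
    coords = np.zeros((X.shape[0], 2))
    coords[:, :nc] = scores
    ev = np.zeros(2)
    ev[:nc] = pca.explained_variance_ratio_
    return Embedding(list(m.sample_ids), coords, (float(ev[0]), float(ev[1])))


def condition_distance(e: Embedding, condition: pd.Series) -> float:
    """Mean Euclidean distance in the 2-D embedding over normal x tumor pairs."""
    condition = condition.reindex(e.sample_ids)
    nmask = (condition == NORMAL).to_numpy()
    tmask = (condition == TUMOR).to_numpy()
    if nmask.sum() == 0 or tmask.sum() == 0:
        raise ValueError("both conditions must be present")
    d = cdist(e.coordinates[nmask], e.coordinates[tmask])
    return float(d.mean())


def sample_distance_matrix(m: ExpressionMatrix, subset: GeneSet | None = None,
                           metric: str = "euclidean",
                           log_transform: bool = True) -> pd.DataFrame:
    """Symmetric sample-by-sample distance matrix on the (sub)matrix."""
    X = _feature_matrix(m, subset, log_transform)
    D = squareform(pdist(X, metric=metric))
    return pd.DataFrame(D, index=m.sample_ids, columns=m.sample_ids)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def _check_distance_matrix(D: np.ndarray) -> None:
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if (D < 0).any():
        raise ValueError("distance matrix must be non-negative")


def nj_tree(d) -> SampleTree:
    """Classical neighbor joining on a symmetric distance matrix.

    Accepts a labelled DataFrame or a square array (leaves then named by
    position). Leaves are processed in sorted-ID order and Q-matrix ties
    break on the lowest (row, column) index pair, so the result is
    deterministic across platforms. Negative branch-length estimates are
    clamped to zero with the deficit moved to the sibling edge; raw
    estimates are kept in ``tree.raw_lengths``. On an additive matrix the
    leaf-to-leaf path lengths of the output reproduce the input exactly.
    """
    if isinstance(d, pd.DataFrame):
        labels = [str(x) for x in d.index]
        D = d.to_numpy(dtype=float)
    else:
        D = np.asarray(d, dtype=float)
        labels = [f"s{i}" for i in range(D.shape[0])]
    _check_distance_matrix(D)
    if D.shape[0] < 3:
        raise ValueError("neighbor joining needs at least 3 leaves")

    order = np.argsort(np.array(labels, dtype=object))
    labels = [labels[i] for i in order]
    D = D[np.ix_(order, order)]

    dist: dict[tuple[str, str], float] = {}
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i < j:
                dist[(a, b)] = dist[(b, a)] = float(D[i, j])

    active = list(labels)
    g = nx.Graph()
    g.add_nodes_from(active)
    raw: dict[tuple[str, str], float] = {}
    new_id = 0

    def clamp_pair(u, a, la, b, lb):
        raw[(a, u)] = la
        raw[(b, u)] = lb
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        g.add_edge(a, u, length=max(la, 0.0))
        g.add_edge(b, u, length=max(lb, 0.0))

    while len(active) > 3:
        n = len(active)
        r = {a: sum(dist[(a, b)] for b in active if b != a) for a in active}
        best = None
        best_q = np.inf
        for i in range(n):
            for j in range(i + 1, n):
                a, b = active[i], active[j]
                q = (n - 2) * dist[(a, b)] - r[a] - r[b]
                if q < best_q - 1e-12:
                    best_q = q
                    best = (a, b)
        a, b = best
        la = 0.5 * dist[(a, b)] + (r[a] - r[b]) / (2.0 * (n - 2))
        lb = dist[(a, b)] - la
        u = f"_nj{new_id}"
        new_id += 1
        clamp_pair(u, a, la, b, lb)
        for c in active:
            if c not in (a, b):
                duc = 0.5 * (dist[(a, c)] + dist[(b, c)] - dist[(a, b)])
                dist[(u, c)] = dist[(c, u)] = duc
        active = [x for x in active if x not in (a, b)] + [u]

    a, b, c = active
    v = f"_nj{new_id}"
    la = 0.5 * (dist[(a, b)] + dist[(a, c)] - dist[(b, c)])
    lb = 0.5 * (dist[(a, b)] + dist[(b, c)] - dist[(a, c)])
    lc = 0.5 * (dist[(a, c)] + dist[(b, c)] - dist[(a, b)])
    for node, ln in ((a, la), (b, lb), (c, lc)):
        raw[(node, v)] = ln
        g.add_edge(node, v, length=max(ln, 0.0))

    return SampleTree(g, raw_lengths=raw)


# ---------------------------------------------------------------------------
# Hierarchical clustering & separation
# ---------------------------------------------------------------------------

def hierarchical_cluster(d):
    """Average-linkage agglomerative dendrogram from a square distance matrix.

    Returns ``(Z, labels)`` where Z is the scipy linkage matrix (merge
    heights are non-decreasing under average linkage on a metric input).
    """
    if isinstance(d, pd.DataFrame):
        labels = [str(x) for x in d.index]
        D = d.to_numpy(dtype=float)
    else:
        D = np.asarray(d, dtype=float)
        labels = [f"s{i}" for i in range(D.shape[0])]
    _check_distance_matrix(D)
    Z = linkage(squareform(D, checks=False), method="average")
    return Z, labels


def _tree_two_cut(tree: SampleTree) -> dict[str, int]:
    """Two-group leaf partition from removing the longest internal edge
    (falling back to the longest edge of any kind)."""
    edges = list(tree.graph.edges(data=True))
    internal = [
        (u, v, d) for u, v, d in edges
        if tree.graph.degree(u) > 1 and tree.graph.degree(v) > 1
    ]
    pool = internal or edges
    u, v, _ = max(pool, key=lambda e: e[2]["length"])
    h = tree.graph.copy()
    h.remove_edge(u, v)
    side = set(nx.node_connected_component(h, u))
    return {leaf: (0 if leaf in side else 1) for leaf in tree.leaves}


def separation_score(obj, condition: pd.Series) -> float:
    """Adjusted Rand index of the 2-cluster cut against condition labels.

    ``obj`` is a SampleTree (cut at the longest internal edge) or a
    ``(Z, labels)`` pair from :func:`hierarchical_cluster` (2-cluster
    fcluster cut). Undefined (NaN) when only one condition is present.
    """
    if isinstance(obj, SampleTree):
        assign = _tree_two_cut(obj)
        ids = sorted(assign)
        pred = [assign[s] for s in ids]
    else:
        Z, ids = obj
        pred = list(fcluster(Z, t=2, criterion="maxclust"))
    truth = condition.reindex(ids)
    if truth.isna().any():
        raise ValueError("condition labels missing for some samples")
    if truth.nunique() < 2:
        warnings.warn("only one condition present: separation undefined", stacklevel=2)
        return float("nan")
    return float(adjusted_rand_score(truth.to_numpy(), pred))
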