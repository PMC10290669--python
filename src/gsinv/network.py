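"""Interaction-network analytics: per-set degree summaries, discrete
power-law fitting of the degree distribution, and induced-subgraph
connectivity.

Degrees are always taken from the *full* graph, then restricted to the set
of interest ("interactions per gene"). Genes in a set but absent from the
graph are excluded from the mean (not counted as degree 0) and reported
separately. "Connectivity" of a set is summarized by both the number of
connected components of its induced subgraph and the fraction of members in
the largest component; the latter is the directional measure (fewer, larger
components = better internally connected).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import optimize, special, stats

from .dataio import GeneSet
from .resample import ResamplingNull, draw_random_set, midrank_percentile

log = logging.getLogger(__name__)


@dataclass
class DegreeReport:
    set_name: str
    mean_degree: float
    degree_values: np.ndarray
    n_genes_in_graph: int
    n_genes_missing: int


@dataclass
class PowerLawFit:
    alpha: float
    xmin: int
    n_tail: int
    loglik: float


@dataclass
class SubgraphReport:
    n_nodes: int
    n_edges: int
    n_components: int
    largest_component_fraction: float
    mean_internal_degree: float


def validate_graph(g: nx.Graph) -> None:
    """Reject directed graphs, self-loops, and handshake-lemma violations."""
    if g.is_directed() or g.is_multigraph():
        raise ValueError("interaction network must be a simple undirected graph")
    loops = list(nx.selfloop_edges(g))
    if loops:
        raise ValueError(f"self-loop at node {loops[0][0]!r}")
    total = sum(d for _, d in g.degree())
    if total != 2 * g.number_of_edges():
        raise ValueError("handshake lemma violated (corrupt graph)")


def degree_report(g: nx.Graph, gene_set: GeneSet | None = None) -> DegreeReport:
    """Mean interactions per gene for a set (or the whole graph)."""
    if gene_set is None:
        members = list(g.nodes)
        name = "all"
    else:
        members = [m for m in gene_set.members if g.has_node(m)]
        name = gene_set.name
    n_missing = 0 if gene_set is None else len(gene_set) - len(members)
    if n_missing:
        log.info("degree_report(%s): %d gene(s) not in graph", name, n_missing)
    degrees = np.array([g.degree(m) for m in members], dtype=float)
    if degrees.size == 0:
        log.warning("degree_report(%s): no genes present in graph", name)
        return DegreeReport(name, float("nan"), degrees, 0, n_missing)
    return DegreeReport(name, float(degrees.mean()), degrees, len(members), n_missing)


def degree_report_excluding(g: nx.Graph, gene_set: GeneSet,
                            excluded: GeneSet) -> DegreeReport:
    """Degree report on ``gene_set`` minus ``excluded`` (e.g. the TF subset)."""
    remaining = tuple(m for m in gene_set.members if m not in set(excluded.members))
    name = f"{gene_set.name}-{excluded.name}"
    if not remaining:
        log.warning("degree_report_excluding: exclusion empties %s", gene_set.name)
        return DegreeReport(name, float("nan"), np.array([]), 0, 0)
    return degree_report(g, GeneSet(name, remaining))


# ---------------------------------------------------------------------------
# Discrete power-law fit
# ---------------------------------------------------------------------------

def _powerlaw_nll(alpha: float, log_sum: float, n: int, xmin: int) -> float:
    return n * np.log(special.zeta(alpha, xmin)) + alpha * log_sum


def fit_power_law(degrees, xmin: int = 1) -> PowerLawFit:
    """Maximum-likelihood exponent of a discrete power law P(k) ~ k^-alpha.

    The tail k >= xmin is used (xmin fixed, default 1); zero degrees are
    never part of the tail. Requires >= 50 tail observations and a
    non-degenerate (non-constant) tail.
    """
    k = np.asarray(degrees)
    if not np.issubdtype(k.dtype, np.integer):
        if not np.allclose(k, np.round(k)):
            raise ValueError("degrees must be integers")
        k = k.astype(np.int64)
    tail = k[k >= max(xmin, 1)]
    if tail.size < 50:
        raise ValueError(f"need >= 50 degrees >= xmin={xmin}, got {tail.size}")
    if np.ptp(tail) == 0:
        raise ValueError("degenerate input: all tail degrees equal")
    log_sum = float(np.sum(np.log(tail)))
    n = int(tail.size)
    res = optimize.minimize_scalar(
        _powerlaw_nll, args=(log_sum, n, xmin), bounds=(1.000001, 25.0),
        method="bounded", options={"xatol": 1e-8},
    )
    alpha = float(res.x)
    return PowerLawFit(alpha=alpha, xmin=int(xmin), n_tail=n,
                       loglik=float(-_powerlaw_nll(alpha, log_sum, n, xmin)))


def powerlaw_loglik_grid(degrees, alphas, xmin: int = 1) -> np.ndarray:
    """Log-likelihood of the tail over a grid of exponents (brute-force aid)."""
    k = np.asarray(degrees, dtype=float)
    tail = k[k >= max(xmin, 1)]
    log_sum = float(np.sum(np.log(tail)))
    return np.array([-_powerlaw_nll(a, log_sum, tail.size, xmin) for a in alphas])


# ---------------------------------------------------------------------------
# Induced subgraphs & density
# ---------------------------------------------------------------------------

def induced_subgraph_report(g: nx.Graph, gene_set: GeneSet) -> SubgraphReport:
    """Component structure of the subgraph induced by a gene set."""
    members = [m for m in gene_set.members if g.has_node(m)]
    sub = g.subgraph(members)
    n = sub.number_of_nodes()
    if n == 0:
        return SubgraphReport(0, 0, 0, float("nan"), float("nan"))
    comps = list(nx.connected_components(sub))
    largest = max(len(c) for c in comps)
    return SubgraphReport(
        n_nodes=n,
        n_edges=sub.number_of_edges(),
        n_components=len(comps),
        largest_component_fraction=largest / n,
        mean_internal_degree=2.0 * sub.number_of_edges() / n,
    )


def degree_density(degrees, grid=None):
    """Gaussian-kernel density of log10 degree, normalized to integrate to 1.

    Returns ``(grid, density)`` on the log10-degree axis; the default grid
    extends three bandwidths past the data range so the mass is captured.
    """
    k = np.asarray(degrees, dtype=float)
    k = k[k > 0]
    if k.size < 2:
        raise ValueError("need at least 2 positive degrees")
    x = np.log10(k)
    kde = stats.gaussian_kde(x)
    if grid is None:
        bw = float(kde.covariance_factor() * x.std(ddof=1)) or 0.1
        grid = np.linspace(x.min() - 4 * bw, x.max() + 4 * bw, 512)
    dens = kde(grid)
    return grid, dens


def mean_degree_null(g: nx.Graph, focal: GeneSet, n_reps: int = 100,
                     seed: int = 0) -> ResamplingNull:
    """Size-matched random-set null for a focal set's mean degree.

    Random sets are drawn from all graph nodes; the focal mean degree is
    located in the null by midrank percentile.
    """
    focal_rep = degree_report(g, focal)
    if focal_rep.n_genes_in_graph < 1:
        raise ValueError("focal set has no genes in the graph")
    rng = np.random.default_rng(seed)
    universe = list(g.nodes)
    values = np.empty(n_reps)
    for i in range(n_reps):
        rand = draw_random_set(universe, focal_rep.n_genes_in_graph, rng)
        values[i] = degree_report(g, rand).mean_degree
    return ResamplingNull(
        statistic_name="mean_degree",
        set_size=focal_rep.n_genes_in_graph,
        n_reps=n_reps,
        values=values,
        focal_value=focal_rep.mean_degree,
        percentile=midrank_percentile(values, focal_rep.mean_degree),
        seed=seed,
    )
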