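"""Synthetic bulk expression, interaction networks, and clustered single-cell
counts with planted, recoverable structure.

Each generator emulates the data regime its downstream analysis expects and
always emits the planted ground truth alongside the data, so recovery tests
never have to re-derive it.

* Bulk: per-gene log-normal baseline means with multiplicative log-normal
  sample noise whose coefficient of variation is condition-specific (tumor
  noisier than normal by default). The focal gene set can be planted as
  statistically exchangeable with the rest (``invariant``), quieter
  (``low_noise``), or with tumor means scaled by a fold change
  (``divergent``).
* Network: a discrete power-law target degree sequence realized by the
  configuration model with self-loops and multi-edges discarded, so the
  exponent is directly plantable; focal nodes' target degrees can be
  boosted, and extra within-focal edges can be planted to make the focal
  induced subgraph preferentially interconnected.
* Single cell: negative-binomial counts (gamma-Poisson mixture) over
  clusters and conditions, with a planted fraction of DE genes per cluster
  of which a fixed share comes from the focal set.

Defaults reflect a small patient cohort (five replicates per condition) at
a few thousand expressed genes, with a focal set sized like a curated
oncogene panel relative to the universe.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .dataio import (CellMatrix, ExpressionMatrix, GeneSet, NORMAL, TUMOR)

log = logging.getLogger(__name__)

FOCAL_MODES = ("invariant", "low_noise", "divergent")


def _require(cond: bool, fieldname: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"{fieldname}: {msg}")


# ---------------------------------------------------------------------------
# Bulk expression
# ---------------------------------------------------------------------------

@dataclass
class BulkSimConfig:
    n_genes: int = 2000
    n_normal: int = 5
    n_tumor: int = 5
    logmean_mu: float = 2.0
    logmean_sigma: float = 1.5
    cv_normal: float = 0.3
    cv_tumor: float = 0.6
    focal_size: int = 100
    focal_mode: str = "invariant"
    focal_effect: float = 1.0
    seed: int = 0

    def __post_init__(self):
        _require(self.n_genes >= 2, "n_genes", "need at least 2 genes")
        _require(self.n_normal >= 2, "n_normal", "need at least 2 samples")
        _require(self.n_tumor >= 2, "n_tumor", "need at least 2 samples")
        _require(self.cv_normal >= 0, "cv_normal", "must be non-negative")
        _require(self.cv_tumor >= 0, "cv_tumor", "must be non-negative")
        _require(0 < self.focal_size < self.n_genes, "focal_size",
                 "must be positive and below n_genes")
        _require(self.focal_mode in FOCAL_MODES, "focal_mode",
                 f"must be one of {FOCAL_MODES}")
        _require(self.focal_effect > 0, "focal_effect", "must be positive")


def _lognormal_noise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Multiplicative log-normal noise with unit mean and the given CV."""
    if cv == 0:
        return np.ones(shape)
    s2 = np.log1p(cv**2)
    return rng.lognormal(mean=-s2 / 2.0, sigma=np.sqrt(s2), size=shape)


def simulate_bulk(config: BulkSimConfig) -> tuple[ExpressionMatrix, GeneSet]:
    """Strictly positive genes x samples TPM-like matrix with a planted focal set.

    Per-gene baseline means m_g ~ LogNormal(logmean_mu, logmean_sigma);
    sample values are m_g times unit-mean multiplicative noise at the
    condition's CV. ``divergent`` multiplies focal tumor means by
    ``focal_effect``; ``low_noise`` divides focal CVs by it; ``invariant``
    leaves the focal genes exchangeable with the rest.
    """
    rng = np.random.default_rng(config.seed)
    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    samples = [f"N{i+1}" for i in range(config.n_normal)] + \
              [f"T{i+1}" for i in range(config.n_tumor)]
    condition = pd.Series(
        [NORMAL] * config.n_normal + [TUMOR] * config.n_tumor, index=samples
    )

    base = rng.lognormal(config.logmean_mu, config.logmean_sigma,
                         size=config.n_genes)
    focal_idx = np.sort(rng.choice(config.n_genes, size=config.focal_size,
                                   replace=False))
    focal_mask = np.zeros(config.n_genes, dtype=bool)
    focal_mask[focal_idx] = True

    means = np.tile(base[:, None], (1, len(samples)))
    if config.focal_mode == "divergent":
        tumor_cols = np.array([condition[s] == TUMOR for s in samples])
        means[np.ix_(focal_mask, tumor_cols)] *= config.focal_effect

    X = np.empty_like(means)
    for j, s in enumerate(samples):
        cv = config.cv_normal if condition[s] == NORMAL else config.cv_tumor
        cvs = np.full(config.n_genes, cv)
        if config.focal_mode == "low_noise":
            cvs[focal_mask] = cv / config.focal_effect
        noise = np.array([_lognormal_noise(rng, c, None) for c in cvs]) \
            if len(set(cvs)) > 1 else _lognormal_noise(rng, cv, config.n_genes)
        X[:, j] = means[:, j] * noise

    m = ExpressionMatrix(pd.DataFrame(X, index=genes, columns=samples), condition)
    focal = GeneSet("focal", tuple(genes[i] for i in focal_idx))
    return m, focal


# ---------------------------------------------------------------------------
# Interaction network
# ---------------------------------------------------------------------------

@dataclass
class NetworkSimConfig:
    n_nodes: int = 2000
    alpha: float = 2.5
    focal_size: int = 100
    focal_degree_boost: float = 1.0
    focal_extra_edges: int = 0
    seed: int = 0

    def __post_init__(self):
        _require(self.n_nodes >= 3, "n_nodes", "need at least 3 nodes")
        _require(self.alpha > 1, "alpha", "power-law exponent must exceed 1")
        _require(0 < self.focal_size < self.n_nodes, "focal_size",
                 "must be positive and below n_nodes")
        _require(self.focal_degree_boost >= 1, "focal_degree_boost",
                 "must be >= 1")
        _require(self.focal_extra_edges >= 0, "focal_extra_edges",
                 "must be non-negative")


def sample_powerlaw_degrees(rng: np.random.Generator, n: int, alpha: float,
                            kmax: int) -> np.ndarray:
    """Draw n degrees from the discrete power law P(k) ~ k^-alpha, 1<=k<=kmax."""
    ks = np.arange(1, kmax + 1, dtype=float)
    pmf = ks**-alpha
    pmf /= pmf.sum()
    return rng.choice(np.arange(1, kmax + 1), size=n, p=pmf)


def simulate_network(config: NetworkSimConfig) -> tuple[nx.Graph, GeneSet]:
    """Scale-free simple graph with an optional planted focal-degree boost.

    Target degrees are drawn from a discrete power law with exponent
    ``alpha`` (capped at n_nodes - 1); focal nodes' targets are multiplied
    by ``focal_degree_boost`` before realization via the configuration
    model, after which self-loops and parallel edges are discarded. An odd
    stub total is repaired by adding a single stub to the first node in
    sorted order (logged, never silent). ``focal_extra_edges`` plants that
    many additional random edges among focal nodes, making the focal
    induced subgraph preferentially interconnected.
    """
    rng = np.random.default_rng(config.seed)
    nodes = [f"g{i:05d}" for i in range(config.n_nodes)]
    kmax = config.n_nodes - 1
    degrees = sample_powerlaw_degrees(rng, config.n_nodes, config.alpha, kmax)

    focal_idx = np.sort(rng.choice(config.n_nodes, size=config.focal_size,
                                   replace=False))
    if config.focal_degree_boost > 1:
        boosted = np.round(degrees[focal_idx] * config.focal_degree_boost)
        degrees[focal_idx] = np.minimum(boosted, kmax).astype(degrees.dtype)

    if degrees.sum() % 2 == 1:
        log.info("simulate_network: odd stub total; adding one stub to %s",
                 nodes[0])
        degrees[0] += 1

    mg = nx.configuration_model(
        degrees.tolist(), seed=int(rng.integers(2**31 - 1))
    )
    g = nx.Graph(mg)  # collapse multi-edges
    g.remove_edges_from(nx.selfloop_edges(g))
    g = nx.relabel_nodes(g, dict(enumerate(nodes)))
    g.add_nodes_from(nodes)

    focal_nodes = [nodes[i] for i in focal_idx]
    if config.focal_extra_edges > 0:
        added = 0
        attempts = 0
        while added < config.focal_extra_edges and attempts < 100 * config.focal_extra_edges:
            a, b = rng.choice(len(focal_nodes), size=2, replace=False)
            u, v = focal_nodes[a], focal_nodes[b]
            attempts += 1
            if not g.has_edge(u, v):
                g.add_edge(u, v)
                added += 1
        if added < config.focal_extra_edges:
            log.warning("simulate_network: planted only %d of %d focal edges",
                        added, config.focal_extra_edges)

    return g, GeneSet("focal", tuple(focal_nodes))


# ---------------------------------------------------------------------------
# Clustered single-cell counts
# ---------------------------------------------------------------------------

@dataclass
class SingleCellSimConfig:
    n_cells_per_cluster_per_condition: int = 100
    n_clusters: int = 3
    n_genes: int = 1000
    nb_mean: float = 2.0
    nb_dispersion: float = 2.0
    de_fraction: float = 0.1
    de_logfc: float = 2.0
    focal_overlap: float = 0.08
    mito_fraction_range: tuple[float, float] = (0.0, 0.1)
    seed: int = 0

    def __post_init__(self):
        _require(self.n_cells_per_cluster_per_condition >= 1,
                 "n_cells_per_cluster_per_condition", "must be positive")
        _require(self.n_clusters >= 1, "n_clusters", "must be positive")
        _require(self.n_genes >= 1, "n_genes", "must be positive")
        _require(self.nb_mean > 0, "nb_mean", "must be positive")
        _require(self.nb_dispersion > 0, "nb_dispersion", "must be positive")
        _require(0 <= self.de_fraction <= 1, "de_fraction", "must lie in [0, 1]")
        _require(0 <= self.focal_overlap <= 1, "focal_overlap",
                 "must lie in [0, 1]")
        lo, hi = self.mito_fraction_range
        _require(0 <= lo <= hi <= 1, "mito_fraction_range",
                 "must be an interval within [0, 1]")


def simulate_single_cell(
    config: SingleCellSimConfig, focal: GeneSet
) -> tuple[CellMatrix, dict]:
    """Clustered negative-binomial counts with planted per-cluster DE genes.

    Per cluster, ``round(de_fraction * n_genes)`` genes receive a tumor
    mean shift of exp(+-de_logfc) (random sign); exactly
    ``round(focal_overlap * n_de)`` of them are drawn from the focal set,
    the rest from non-focal genes, so the planted focal share is an exact
    construction identity. Returns the cell matrix and the ground truth
    ``{cluster: sorted planted gene list}``.
    """
    genes = [f"g{i:05d}" for i in range(config.n_genes)]
    gene_index = {g: i for i, g in enumerate(genes)}
    focal_in = [g for g in focal.members if g in gene_index]
    n_de = int(round(config.de_fraction * config.n_genes))
    n_focal_de = int(round(config.focal_overlap * n_de))
    if n_focal_de > len(focal_in):
        raise ValueError(
            f"focal set too small: need {n_focal_de} focal DE genes per "
            f"cluster but only {len(focal_in)} focal genes are in the matrix"
        )

    rng = np.random.default_rng(config.seed)
    # per-gene baseline means (unit-mean log-normal spread around nb_mean)
    spread = 0.5
    base = config.nb_mean * rng.lognormal(-spread**2 / 2, spread,
                                          size=config.n_genes)
    r = config.nb_dispersion

    nonfocal_in = [g for g in genes if g not in set(focal_in)]
    if n_de - n_focal_de > len(nonfocal_in):
        raise ValueError(
            f"focal_overlap: need {n_de - n_focal_de} non-focal DE genes per "
            f"cluster but only {len(nonfocal_in)} genes are outside the focal set"
        )
    clusters = [f"c{j}" for j in range(config.n_clusters)]
    truth: dict[str, list[str]] = {}
    blocks, cell_ids, cl_lab, cond_lab = [], [], [], []
    ncc = config.n_cells_per_cluster_per_condition

    for cluster in clusters:
        # mild cluster identity: per-gene modulation shared by both conditions
        mod = rng.lognormal(-0.3**2 / 2, 0.3, size=config.n_genes)
        mu = base * mod

        if n_de > 0:
            de_focal = rng.choice(len(focal_in), size=n_focal_de, replace=False)
            de_nonfocal = rng.choice(len(nonfocal_in),
                                     size=n_de - n_focal_de, replace=False)
            planted = [focal_in[i] for i in de_focal] + \
                      [nonfocal_in[i] for i in de_nonfocal]
        else:
            planted = []
        truth[cluster] = sorted(planted)

        mu_tumor = mu.copy()
        if planted and config.de_logfc != 0:
            # Mass-balanced signs: choose the up-regulation probability so the
            # planted genes' total expected expression is conserved, then
            # rescale exactly. Otherwise the planted effect would shift tumor
            # library sizes and, after per-cell normalization, drag every
            # unplanted gene along as a compositional false positive.
            el = np.exp(config.de_logfc)
            p_up = (1.0 - 1.0 / el) / (el - 1.0 / el)
            signs = np.where(rng.random(len(planted)) < p_up, 1.0, -1.0)
            idx = np.array([gene_index[g] for g in planted])
            mult = np.exp(signs * config.de_logfc)
            mult *= mu[idx].sum() / (mu[idx] * mult).sum()
            mu_tumor[idx] *= mult

        for cond, mu_c in ((NORMAL, mu), (TUMOR, mu_tumor)):
            lam = rng.gamma(shape=r, scale=mu_c / r, size=(ncc, config.n_genes))
            counts = rng.poisson(lam)
            blocks.append(counts)
            for i in range(ncc):
                cell_ids.append(f"{cluster}_{cond[0]}{i+1}")
            cl_lab.extend([cluster] * ncc)
            cond_lab.extend([cond] * ncc)

    lo, hi = config.mito_fraction_range
    n_cells = len(cell_ids)
    mito = rng.uniform(lo, hi, size=n_cells) if hi > lo else np.full(n_cells, lo)

    cm = CellMatrix(
        counts=np.vstack(blocks).astype(np.int64),
        cell_ids=cell_ids,
        gene_ids=genes,
        cluster=np.array(cl_lab),
        condition=np.array(cond_lab),
        mito_fraction=mito,
    )
    return cm, truth
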