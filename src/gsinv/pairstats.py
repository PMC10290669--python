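"""Pairwise sample statistics over gene subsets: Pearson r, Spearman rho,
binned mutual information, and expression noise (squared coefficient of
variation), aggregated over sample-pair groups.

All four statistics compare two *samples* across a common set of genes.
Sample pairs are grouped as normal-vs-normal (``NvsN``), tumor-vs-tumor
(``TvsT``) and all normal x tumor cross pairs (``NvsT``), and the group mean
of each statistic is reported — the layout of a correlation/noise summary
table with one row per gene subset.

Conventions fixed here (the source formulas leave them open):

* Spearman rho is computed as Pearson on midranks, the standard tie-safe
  convention, rather than the no-ties rank-difference formula.
* Noise eta^2 uses the population (divide-by-n) variance, so for a pair of
  samples eta^2_i = (x_i - y_i)^2 / (x_i + y_i)^2 — the CV^2 convention.
* Mutual information is the plain plugin estimate (no bias-correction term)
  in nats, on rank-transformed values cut into equal-count bins; the bin
  count comes from Doane's rule applied to the pooled midranks.
* Statistics are computed on the abundance scale as given; an optional
  log2(x+1) pre-transform is available in :func:`aggregate_pairs`.
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from .dataio import ExpressionMatrix, GeneSet, NORMAL, TUMOR

log = logging.getLogger(__name__)

GROUPS = ("NvsN", "TvsT", "NvsT")
STATISTICS = ("r", "rho", "mi", "eta2")


@dataclass
class PairStatReport:
    """Group-averaged pairwise statistics for one gene subset."""

    gene_subset: str
    group: str
    r: float
    rho: float
    mi: float
    eta2: float
    n_pairs: int


# ---------------------------------------------------------------------------
# Elementary statistics
# ---------------------------------------------------------------------------

def pearson_r(x, y) -> float:
    """Pearson correlation between two samples over n >= 3 genes.

    A constant vector has undefined correlation; NaN is returned with a
    warning rather than raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 genes")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector: Pearson correlation undefined", stacklevel=2)
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def spearman_rho(x, y) -> float:
    """Spearman rank correlation: Pearson on midranks (tie-safe)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 genes")
    return pearson_r(stats.rankdata(x), stats.rankdata(y))


def doane_bins(values) -> int:
    """Histogram bin count by Doane's rule.

    k = ceil(1 + log2 n + log2(1 + |g1| / sigma_g1)) with g1 the sample
    skewness and sigma_g1 = sqrt(6(n-2) / ((n+1)(n+3))); at least 2 bins.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 4:
        raise ValueError("Doane's rule needs at least 4 observations")
    g1 = stats.skew(v)
    if not np.isfinite(g1):  # constant input
        g1 = 0.0
    sigma_g1 = math.sqrt(6.0 * (n - 2) / ((n + 1.0) * (n + 3.0)))
    k = math.ceil(1.0 + math.log2(n) + math.log2(1.0 + abs(g1) / sigma_g1))
    return max(int(k), 2)


def _equal_count_bins(ranks: np.ndarray, k: int) -> np.ndarray:
    """Assign midranks in [1, n] to k near-equal-count bins (0..k-1)."""
    n = ranks.size
    idx = np.ceil(ranks * k / n).astype(int) - 1
    return np.clip(idx, 0, k - 1)


def _mi_from_joint(joint: np.ndarray) -> float:
    """Plugin mutual information (nats) from a joint count table."""
    joint = np.asarray(joint, dtype=float)
    n = joint.sum()
    if n == 0:
        return 0.0
    pxy = joint / n
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    mi = float(np.sum(pxy[nz] * np.log(pxy[nz] / (px @ py)[nz])))
    return max(mi, 0.0)


def mutual_information(x, y) -> float:
    """Plugin mutual information between two samples, in nats.

    Both vectors are rank-transformed; the common bin count k comes from
    Doane's rule on the pooled midranks (using the per-vector n in the
    log2 n term); ranks are cut into k equal-count bins and the joint and
    marginal frequencies give the plugin estimate. Degenerate binning
    returns 0 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 4:
        raise ValueError("need two equal-length vectors of at least 4 genes")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = x.size
    pooled = np.concatenate([rx, ry])
    g1 = stats.skew(pooled)
    if not np.isfinite(g1):
        g1 = 0.0
    sigma_g1 = math.sqrt(6.0 * (n - 2) / ((n + 1.0) * (n + 3.0)))
    k = math.ceil(1.0 + math.log2(n) + math.log2(1.0 + abs(g1) / sigma_g1))
    k = int(min(max(k, 2), n))
    bx = _equal_count_bins(rx, k)
    by = _equal_count_bins(ry, k)
    if len(np.unique(bx)) < 2 or len(np.unique(by)) < 2:
        warnings.warn("degenerate binning: mutual information set to 0", stacklevel=2)
        return 0.0
    joint = np.bincount(bx * k + by, minlength=k * k).reshape(k, k)
    return _mi_from_joint(joint)


def gene_noise(xi: float, yi: float) -> float:
    """Noise of one gene across a sample pair: population variance over
    squared mean, i.e. (x - y)^2 / (x + y)^2."""
    mu = (xi + yi) / 2.0
    if mu == 0:
        raise ValueError("gene noise undefined at zero mean")
    var = ((xi - mu) ** 2 + (yi - mu) ** 2) / 2.0
    return float(var / mu**2)


def total_noise(x, y) -> float:
    """Average noise over genes between two samples.

    Genes at zero expression in both samples have undefined noise and are
    excluded (their count is logged).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    mu = (x + y) / 2.0
    valid = mu != 0
    n_excluded = int((~valid).sum())
    if n_excluded:
        log.info("total_noise: excluded %d gene(s) with zero mean", n_excluded)
    if valid.sum() == 0:
        raise ValueError("all genes have zero expression in both samples")
    eta2 = (x[valid] - y[valid]) ** 2 / (x[valid] + y[valid]) ** 2
    return float(eta2.mean())


# ---------------------------------------------------------------------------
# Group aggregation
# ---------------------------------------------------------------------------

def pair_indices(m: ExpressionMatrix, group: str) -> list[tuple[int, int]]:
    """Column index pairs of the requested sample-pair group."""
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    cols = {s: i for i, s in enumerate(m.sample_ids)}
    normals = [cols[s] for s in m.samples_of(NORMAL)]
    tumors = [cols[s] for s in m.samples_of(TUMOR)]
    if group == "NvsN":
        return list(combinations(normals, 2))
    if group == "TvsT":
        return list(combinations(tumors, 2))
    return [(a, b) for a in normals for b in tumors]


def _mean_stat_over_pairs(X: np.ndarray, pairs, stat: str) -> float:
    """Mean of one statistic over the given column pairs of a genes x samples
    array. Vectorized for r/rho/eta2; mi loops over pairs."""
    ia = np.array([p[0] for p in pairs])
    ib = np.array([p[1] for p in pairs])
    if stat in ("r", "rho"):
        Z = stats.rankdata(X, axis=0) if stat == "rho" else X
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            C = np.corrcoef(Z, rowvar=False)
        C = np.atleast_2d(C)
        return float(np.mean(C[ia, ib]))
    if stat == "eta2":
        A, B = X[:, ia], X[:, ib]
        s = A + B
        with np.errstate(divide="ignore", invalid="ignore"):
            eta2 = np.where(s != 0, (A - B) ** 2 / s**2, np.nan)
        return float(np.nanmean(eta2, axis=0).mean())
    if stat == "mi":
        return float(np.mean([mutual_information(X[:, a], X[:, b]) for a, b in pairs]))
    raise ValueError(f"unknown statistic {stat!r}")


def aggregate_pairs(
    m: ExpressionMatrix,
    group: str,
    subset: GeneSet | None = None,
    log_transform: bool = False,
) -> PairStatReport:
    """All four statistics on a gene subset, averaged over a sample-pair group.

    ``subset=None`` uses the whole matrix. Requires at least two samples in
    every condition the group references.
    """
    sub = m if subset is None else m.subset(subset)
    pairs = pair_indices(sub, group)
    if not pairs:
        raise ValueError(f"group {group} has no sample pairs "
                         "(need >= 2 samples per referenced condition)")
    X = sub.values
    if log_transform:
        X = np.log2(X + 1.0)
    return PairStatReport(
        gene_subset=subset.name if subset is not None else "whole",
        group=group,
        r=_mean_stat_over_pairs(X, pairs, "r"),
        rho=_mean_stat_over_pairs(X, pairs, "rho"),
        mi=_mean_stat_over_pairs(X, pairs, "mi"),
        eta2=_mean_stat_over_pairs(X, pairs, "eta2"),
        n_pairs=len(pairs),
    )


def report_table(m: ExpressionMatrix, subsets: list[GeneSet | None],
                 log_transform: bool = False):
    """Summary table: rows = gene subsets, columns = statistic x group."""
    import pandas as pd

    rows = {}
    for subset in subsets:
        name = subset.name if subset is not None else "whole"
        row = {}
        for group in GROUPS:
            rep = aggregate_pairs(m, group, subset, log_transform=log_transform)
            for stat in STATISTICS:
                row[f"{stat}:{group}"] = getattr(rep, stat)
        rows[name] = row
    return pd.DataFrame.from_dict(rows, orient="index")
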