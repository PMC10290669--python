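"""Size-matched random-gene-set resampling nulls.

The invariance question — does a focal gene set behave differently from
arbitrary genes? — is answered against a null distribution built by drawing
random gene sets of the same size from the expressed-gene universe (default
100 draws) and evaluating the statistic of interest on each. The focal set's
empirical percentile locates it within that null; "invariant" means typical
(central) percentiles across statistics.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .dataio import ExpressionMatrix, GeneSet
from . import pairstats

log = logging.getLogger(__name__)


@dataclass
class ResamplingNull:
    statistic_name: str
    set_size: int
    n_reps: int
    values: np.ndarray
    focal_value: float
    percentile: float
    seed: int

    def central(self, mass: float = 0.9) -> bool:
        """Whether the focal percentile lies in the central ``mass`` band."""
        lo = (1.0 - mass) / 2.0
        return lo <= self.percentile <= 1.0 - lo


def midrank_percentile(values, focal_value: float) -> float:
    """Empirical percentile of ``focal_value`` within ``values``.

    Midrank convention: (#{below} + 0.5 #{equal}) / len(values), so a focal
    value below a single draw scores 0, equal scores 0.5, above scores 1.
    """
    values = np.asarray(values, dtype=float)
    below = np.sum(values < focal_value)
    equal = np.sum(values == focal_value)
    return float((below + 0.5 * equal) / values.size)


def draw_random_set(universe, size: int, rng: np.random.Generator,
                    name: str = "random") -> GeneSet:
    """Uniform sample of ``size`` genes without replacement.

    The universe is sorted before drawing so the draw depends only on the
    seed and the universe *contents*, not on input ordering.
    """
    universe = sorted(universe)
    if size > len(universe):
        raise ValueError(f"requested size {size} exceeds universe of {len(universe)}")
    idx = rng.choice(len(universe), size=size, replace=False)
    return GeneSet(name, tuple(universe[i] for i in idx))


def _parse_statistic(statistic):
    """Accept 'stat:group' strings or a callable(matrix, gene_tuple) -> float."""
    if callable(statistic):
        return getattr(statistic, "__name__", "custom"), statistic
    stat, _, group = statistic.partition(":")
    if stat not in pairstats.STATISTICS or group not in pairstats.GROUPS:
        raise ValueError(
            f"statistic must be 'stat:group' with stat in {pairstats.STATISTICS} "
            f"and group in {pairstats.GROUPS}, or a callable; got {statistic!r}"
        )

    def fn(m: ExpressionMatrix, genes: tuple) -> float:
        sub = m.subset(genes)
        pairs = pairstats.pair_indices(sub, group)
        return pairstats._mean_stat_over_pairs(sub.values, pairs, stat)

    return statistic, fn


def build_nulls(
    m: ExpressionMatrix,
    focal: GeneSet,
    statistics,
    n_reps: int = 100,
    seed: int = 0,
    exclude_focal: bool = False,
) -> dict[str, ResamplingNull]:
    """Build nulls for several statistics from one shared set of random draws.

    All statistics are evaluated on the same ``n_reps`` size-matched draws,
    so their percentiles are comparable replicate by replicate. Focal genes
    absent from the matrix are dropped (logged) and the matched size is the
    intersection; by default focal genes stay inside the sampling universe.
    """
    present = tuple(g for g in focal.members if g in set(m.gene_ids))
    n_dropped = len(focal) - len(present)
    if n_dropped:
        log.info("build_nulls: %d focal gene(s) absent from matrix", n_dropped)
    if len(present) < 3:
        raise ValueError("focal set has fewer than 3 genes in the matrix")
    focal_present = GeneSet(focal.name, present)

    universe = set(m.gene_ids)
    if exclude_focal:
        universe -= set(present)
    rng = np.random.default_rng(seed)

    named = [_parse_statistic(s) for s in statistics]
    focal_values = {name: fn(m, present) for name, fn in named}
    draws = np.empty((len(named), n_reps))
    for rep in range(n_reps):
        rand = draw_random_set(universe, len(present), rng)
        for j, (_, fn) in enumerate(named):
            draws[j, rep] = fn(m, rand.members)

    out = {}
    for j, (name, _) in enumerate(named):
        fv = focal_values[name]
        out[name] = ResamplingNull(
            statistic_name=name,
            set_size=len(present),
            n_reps=n_reps,
            values=draws[j].copy(),
            focal_value=fv,
            percentile=midrank_percentile(draws[j], fv),
            seed=seed,
        )
    return out


def build_null(
    m: ExpressionMatrix,
    focal: GeneSet,
    statistic="eta2:NvsT",
    n_reps: int = 100,
    seed: int = 0,
    exclude_focal: bool = False,
) -> ResamplingNull:
    """Single-statistic convenience wrapper around :func:`build_nulls`."""
    name, _ = _parse_statistic(statistic)
    return build_nulls(m, focal, [statistic], n_reps=n_reps, seed=seed,
                       exclude_focal=exclude_focal)[name]
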