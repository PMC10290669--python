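"""Per-sample distribution fitting with AIC model selection, and fitted-tail
low-expression filtering.

Each sample's positive abundances are fitted by maximum likelihood to five
heavy-tailed candidate families — log-normal, Pareto, Burr (type XII,
three-parameter), log-logistic (the two-parameter Burr special case), and
Weibull — and the family with the minimum AIC wins. The low-expression
filter turns the qualitative idea of "thresholds where the data leave the
fitted distribution" into a concrete rule: per sample, the threshold is the
q-quantile of that sample's best-fitting distribution, and a gene is kept
if it exceeds the threshold in at least ``min_sample_frac`` of samples.

Zeros are excluded from fitting (count reported) but genes are filtered on
their raw values.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dataio import ExpressionMatrix

log = logging.getLogger(__name__)

#: fixed family order — also the final tie-break in model selection
FAMILIES = ("log-normal", "Pareto", "Burr", "loglogistic", "Weibull")

_SCIPY_DIST = {
    "log-normal": stats.lognorm,
    "Pareto": stats.pareto,
    "Burr": stats.burr12,
    "loglogistic": stats.fisk,
    "Weibull": stats.weibull_min,
}
#: free parameters per family (location fixed at 0 throughout)
N_PARAMS = {"log-normal": 2, "Pareto": 2, "Burr": 3, "loglogistic": 2, "Weibull": 2}


@dataclass
class DistributionFit:
    family: str
    params: tuple | None
    loglik: float
    aic: float
    n: int
    failed: bool = False


def _fit_family(family: str, x: np.ndarray) -> tuple:
    """MLE parameters (scipy convention: shapes, loc, scale) with loc=0."""
    dist = _SCIPY_DIST[family]
    if family == "log-normal":  # closed form
        lx = np.log(x)
        return (float(lx.std(ddof=0)), 0.0, float(np.exp(lx.mean())))
    if family == "Pareto":  # closed form: xm = min, b = n / sum log(x/xm)
        xm = float(x.min())
        b = x.size / float(np.sum(np.log(x / xm)))
        return (b, 0.0, xm)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if family == "Burr":
            # seed from the nested log-logistic fit (Burr with d = 1)
            c0, _, s0 = stats.fisk.fit(x, floc=0)
            return dist.fit(x, c0, 1.0, floc=0, scale=s0)
        return dist.fit(x, floc=0)


def fit_distributions(values, min_n: int = 50) -> list[DistributionFit]:
    """Fit all candidate families to strictly positive abundances.

    Zeros (and missing values) are dropped before fitting and their count
    logged. Families whose optimization fails or yields a non-finite
    likelihood are returned flagged as failed, never fabricated.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    n_zero = int((v <= 0).sum())
    x = v[v > 0]
    if n_zero:
        log.info("fit_distributions: excluded %d zero/negative value(s)", n_zero)
    if x.size == 0:
        raise ValueError("all values are zero: nothing to fit")
    if x.size < min_n:
        raise ValueError(f"need >= {min_n} positive values, got {x.size}")

    fits = []
    for family in FAMILIES:
        k = N_PARAMS[family]
        try:
            params = _fit_family(family, x)
            ll = float(np.sum(_SCIPY_DIST[family].logpdf(x, *params)))
            if not np.isfinite(ll):
                raise FloatingPointError("non-finite log-likelihood")
            fits.append(DistributionFit(family, tuple(params), ll,
                                        2.0 * k - 2.0 * ll, x.size))
        except Exception as exc:  # noqa: BLE001 — any optimizer failure
            log.warning("fit_distributions: %s fit failed (%s)", family, exc)
            fits.append(DistributionFit(family, None, float("nan"),
                                        float("nan"), x.size, failed=True))
    return fits


def select_best(fits: list[DistributionFit]) -> DistributionFit:
    """Minimum-AIC fit; ties break on fewer parameters, then family order."""
    ok = [f for f in fits if not f.failed and np.isfinite(f.aic)]
    if not ok:
        raise ValueError("no successful fits to select from")
    return min(ok, key=lambda f: (f.aic, N_PARAMS[f.family],
                                  FAMILIES.index(f.family)))


def fitted_quantile(fit: DistributionFit, q: float) -> float:
    """q-quantile of a fitted distribution."""
    return float(_SCIPY_DIST[fit.family].ppf(q, *fit.params))


def filter_low_expression(m: ExpressionMatrix, q: float = 0.05,
                          min_sample_frac: float = 0.5) -> ExpressionMatrix:
    """Drop genes below the fitted per-sample q-quantile in too many samples.

    For each sample the best-AIC fitted distribution provides a threshold
    (its q-quantile); a gene is retained if its raw value exceeds the
    threshold in at least ``min_sample_frac`` of samples. Monotone in q:
    a larger q never retains more genes.
    """
    if not 0 < q < 0.5:
        raise ValueError("q must lie in (0, 0.5)")
    X = m.values
    thresholds = np.empty(m.n_samples)
    for j in range(m.n_samples):
        best = select_best(fit_distributions(X[:, j]))
        thresholds[j] = fitted_quantile(best, q)
        log.info("filter_low_expression: sample %s best=%s threshold=%.4g",
                 m.sample_ids[j], best.family, thresholds[j])
    above = (X > thresholds[None, :])
    keep = above.mean(axis=1) >= min_sample_frac
    log.info("filter_low_expression: retained %d of %d genes",
             int(keep.sum()), m.n_genes)
    if keep.sum() == 0:
        log.warning("filter_low_expression: no genes retained")
    return ExpressionMatrix(m.data.loc[keep], m.condition.copy())
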