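"""Single-cell stage: QC filtering, log-normalization, per-cluster
tumor-vs-normal differential expression, and the focal-set fraction among
DE genes.

Cells are kept when they detect more than ``min_genes`` unique genes and
carry less than ``max_mito`` mitochondrial counts. Counts are normalized
per cell as ln(1 + count / total * 10000). Within each cluster, genes
detected in at least half the cells of either condition group are compared
by a two-sided Wilcoxon rank-sum test on normalized values, with
Benjamini-Hochberg adjustment across the tested genes of that cluster;
"significant" means adjusted p < 0.05. Cluster labels are taken as given —
clustering itself is upstream of this module.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dataio import CellMatrix, GeneSet, NORMAL, TUMOR

log = logging.getLogger(__name__)

DE_COLUMNS = ["cluster", "gene", "p_value", "adjusted_p", "log_fc",
              "pct_tumor", "pct_normal"]


def qc_filter(cm: CellMatrix, min_genes: int = 200,
              max_mito: float = 0.15) -> CellMatrix:
    """Keep cells with > min_genes detected genes and mito fraction < max_mito."""
    detected = (cm.counts > 0).sum(axis=1)
    keep = (detected > min_genes) & (cm.mito_fraction < max_mito)
    n_removed = int((~keep).sum())
    log.info("qc_filter: removed %d of %d cells", n_removed, cm.n_cells)
    return CellMatrix(
        counts=cm.counts[keep],
        cell_ids=[c for c, k in zip(cm.cell_ids, keep) if k],
        gene_ids=list(cm.gene_ids),
        cluster=cm.cluster[keep],
        condition=cm.condition[keep],
        mito_fraction=cm.mito_fraction[keep],
    )


def log_normalize(cm: CellMatrix, scale_factor: float = 10000.0) -> np.ndarray:
    """Per-cell normalization: ln(1 + count / total_counts * scale_factor)."""
    totals = cm.counts.sum(axis=1).astype(float)
    if (totals == 0).any():
        raise ValueError("cell with zero total counts; run qc_filter first")
    return np.log1p(cm.counts / totals[:, None] * scale_factor)


def cluster_de(cm: CellMatrix, norm: np.ndarray, cluster,
               min_pct: float = 0.5, min_cells: int = 3) -> pd.DataFrame:
    """Tumor-vs-normal Wilcoxon rank-sum DE within one cluster.

    Genes detected (count > 0) in >= min_pct of cells in at least one
    condition group are tested; p-values are BH-adjusted within the
    cluster. log_fc is the difference of ln(1 + mean normalized expression)
    between tumor and normal. Returns an empty frame (with a log entry)
    when either condition has fewer than ``min_cells`` cells.
    """
    in_cluster = cm.cluster == cluster
    tmask = in_cluster & (cm.condition == TUMOR)
    nmask = in_cluster & (cm.condition == NORMAL)
    if tmask.sum() < min_cells or nmask.sum() < min_cells:
        log.info("cluster_de: cluster %r skipped (%d tumor / %d normal cells)",
                 cluster, int(tmask.sum()), int(nmask.sum()))
        return pd.DataFrame(columns=DE_COLUMNS)

    pct_t = (cm.counts[tmask] > 0).mean(axis=0)
    pct_n = (cm.counts[nmask] > 0).mean(axis=0)
    tested = np.maximum(pct_t, pct_n) >= min_pct
    if tested.sum() == 0:
        log.info("cluster_de: cluster %r has no genes passing min_pct", cluster)
        return pd.DataFrame(columns=DE_COLUMNS)

    xt = norm[tmask][:, tested]
    xn = norm[nmask][:, tested]
    res = stats.mannwhitneyu(xt, xn, alternative="two-sided", axis=0)
    pvals = np.asarray(res.pvalue, dtype=float)
    _, adj, _, _ = multipletests(pvals, method="fdr_bh")
    lfc = np.log1p(xt.mean(axis=0)) - np.log1p(xn.mean(axis=0))
    genes = np.asarray(cm.gene_ids)[tested]
    return pd.DataFrame(
        {
            "cluster": cluster,
            "gene": genes,
            "p_value": pvals,
            "adjusted_p": adj,
            "log_fc": lfc,
            "pct_tumor": pct_t[tested],
            "pct_normal": pct_n[tested],
        }
    )


def de_all_clusters(cm: CellMatrix, norm: np.ndarray | None = None,
                    min_pct: float = 0.5) -> pd.DataFrame:
    """Run :func:`cluster_de` over every cluster present in both conditions."""
    if norm is None:
        norm = log_normalize(cm)
    frames = [cluster_de(cm, norm, c, min_pct=min_pct)
              for c in sorted(set(cm.cluster))]
    frames = [f for f in frames if len(f)]
    if not frames:
        return pd.DataFrame(columns=DE_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def focal_fraction(de: pd.DataFrame, focal: GeneSet,
                   alpha: float = 0.05) -> dict:
    """Fraction of significant DE genes that belong to the focal set.

    Per cluster: significant (cluster, gene) records intersected with the
    focal set. Overall: the union of significant genes across clusters.
    Clusters (or the overall pool) with no significant genes report 0 and
    are flagged in ``empty``.
    """
    focal_members = set(focal.members)
    sig = de[de["adjusted_p"] < alpha] if len(de) else de
    per_cluster = {}
    empty = []
    for cluster in sorted(set(de["cluster"])) if len(de) else []:
        genes = set(sig[sig["cluster"] == cluster]["gene"])
        if not genes:
            per_cluster[cluster] = 0.0
            empty.append(cluster)
        else:
            per_cluster[cluster] = len(genes & focal_members) / len(genes)
    all_sig = set(sig["gene"]) if len(sig) else set()
    if not all_sig:
        empty.append("overall")
    overall = (len(all_sig & focal_members) / len(all_sig)) if all_sig else 0.0
    return {
        "per_cluster": per_cluster,
        "overall": overall,
        "n_significant": len(all_sig),
        "empty": empty,
    }
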