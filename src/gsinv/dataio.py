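"""Validated containers and readers/writers for every external format the pipeline touches.

Gene identifiers are opaque strings matched case-sensitively; no symbol/alias
mapping is attempted (ID harmonization across databases is the caller's job).
Missing proteomic abundances may be encoded as an empty field or ``NA``.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import networkx as nx
import scipy.io
import scipy.sparse

log = logging.getLogger(__name__)

NORMAL = "normal"
TUMOR = "tumor"
CONDITIONS = (NORMAL, TUMOR)


@dataclass(frozen=True)
class GeneSet:
    """A named collection of unique gene identifiers."""

    name: str
    members: tuple[str, ...]

    def __post_init__(self):
        if len(self.members) == 0:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"gene set {self.name!r} contains duplicate members")
        object.__setattr__(self, "members", tuple(str(m) for m in self.members))

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.members)

    def __iter__(self):
        return iter(self.members)


@dataclass
class ExpressionMatrix:
    """Genes x samples abundance matrix with per-sample condition labels.

    ``data`` holds genes in rows (unique index) and samples in columns
    (unique header); ``condition`` maps every sample to ``normal`` or
    ``tumor``. Values are finite or explicitly missing (NaN, proteomics).
    """

    data: pd.DataFrame
    condition: pd.Series

    def __post_init__(self):
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate gene identifier: {dup!r}")
        if self.data.columns.duplicated().any():
            dup = self.data.columns[self.data.columns.duplicated()][0]
            raise ValueError(f"duplicate sample identifier: {dup!r}")
        missing = [s for s in self.data.columns if s not in self.condition.index]
        if missing:
            raise ValueError(f"sample {missing[0]!r} has no condition label")
        self.condition = self.condition.reindex(self.data.columns)
        bad = set(self.condition.unique()) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown condition label(s): {sorted(bad)}")
        vals = self.data.to_numpy(dtype=float)
        if np.isinf(vals).any():
            raise ValueError("expression values must be finite or missing (NaN)")

    # -- convenience accessors -------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def samples_of(self, condition: str) -> list[str]:
        return list(self.condition.index[self.condition == condition])

    def subset(self, genes) -> "ExpressionMatrix":
        """Restrict to the given genes (GeneSet or iterable), matrix order kept."""
        if isinstance(genes, GeneSet):
            genes = genes.members
        keep = self.data.index.intersection(list(genes), sort=False)
        return ExpressionMatrix(self.data.loc[keep], self.condition.copy())


@dataclass
class CellMatrix:
    """Cell x gene integer count matrix with per-cell annotations."""

    counts: np.ndarray  # cells x genes, non-negative integers
    cell_ids: list[str]
    gene_ids: list[str]
    cluster: np.ndarray  # per-cell labels
    condition: np.ndarray  # per-cell {normal, tumor}
    mito_fraction: np.ndarray  # per-cell in [0, 1]

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValueError("counts shape does not match cell/gene id lengths")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        self.cluster = np.asarray(self.cluster)
        self.condition = np.asarray(self.condition)
        self.mito_fraction = np.asarray(self.mito_fraction, dtype=float)
        for name, arr in (("cluster", self.cluster), ("condition", self.condition),
                          ("mito_fraction", self.mito_fraction)):
            if len(arr) != len(self.cell_ids):
                raise ValueError(f"{name} length does not match number of cells")
        if ((self.mito_fraction < 0) | (self.mito_fraction > 1)).any():
            raise ValueError("mito_fraction must lie in [0, 1]")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

def _sep_for(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_expression(path, condition_path) -> ExpressionMatrix:
    """Read a genes x samples TSV/CSV plus a sample->condition map.

    The matrix file must have a header row of sample IDs and gene IDs in the
    first column. The condition file is two columns (sample, condition) with
    or without a header; every sample in the matrix must be mapped.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=_sep_for(path), index_col=0,
                         na_values=["NA"], keep_default_na=False)
    except Exception as exc:  # noqa: BLE001
        raise ValueError(f"malformed expression matrix {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise ValueError(f"malformed header in {path}: no sample columns")
    df = df.apply(pd.to_numeric, errors="coerce")

    cond = _read_condition_table(condition_path)
    return ExpressionMatrix(df, cond)


def _read_condition_table(path) -> pd.Series:
    path = Path(path)
    raw = pd.read_csv(path, sep=_sep_for(path), header=None, dtype=str)
    if raw.shape[1] < 2:
        raise ValueError(f"condition file {path} needs two columns (sample, condition)")
    if str(raw.iloc[0, 1]).lower() in CONDITIONS:
        body = raw
    else:  # header row present
        body = raw.iloc[1:]
    return pd.Series(body.iloc[:, 1].str.lower().values, index=body.iloc[:, 0].values)


def write_expression(m: ExpressionMatrix, path, condition_path) -> None:
    m.data.to_csv(path, sep=_sep_for(path))
    pd.DataFrame({"sample": m.sample_ids, "condition": m.condition.values}).to_csv(
        condition_path, sep=_sep_for(condition_path), index=False, header=False
    )


def drop_missing_genes(m: ExpressionMatrix) -> ExpressionMatrix:
    """Remove every gene with at least one missing value (proteomics rule)."""
    keep = ~m.data.isna().any(axis=1)
    n_removed = int((~keep).sum())
    log.info("drop_missing_genes: removed %d of %d genes", n_removed, m.n_genes)
    if keep.sum() == 0:
        log.warning("drop_missing_genes: no genes remain")
    return ExpressionMatrix(m.data.loc[keep], m.condition.copy())


# ---------------------------------------------------------------------------
# Gene sets (GMT or one-ID-per-line)
# ---------------------------------------------------------------------------

def read_gene_set(path, name: str | None = None) -> GeneSet:
    path = Path(path)
    lines = [ln.rstrip("\n") for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty gene set file")
    if "\t" in lines[0]:
        fields = lines[0].split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:1: GMT line needs name, description, >=1 gene")
        set_name, genes = fields[0], fields[2:]
    else:
        set_name, genes = path.stem, lines
    seen, members = set(), []
    for g in genes:
        if g not in seen:
            seen.add(g)
            members.append(g)
    return GeneSet(name or set_name, tuple(members))


def write_gene_set(gs: GeneSet, path) -> None:
    Path(path).write_text(gs.name + "\tna\t" + "\t".join(gs.members) + "\n")


# ---------------------------------------------------------------------------
# Interaction networks (two-column edge lists)
# ---------------------------------------------------------------------------

def read_edge_list(path) -> nx.Graph:
    """Read an undirected edge list, deduplicating unordered pairs.

    ``(A, B)`` and ``(B, A)`` collapse to one edge; self-loops are dropped
    with a log entry. Parse failures report the offending line number.
    """
    g = nx.Graph()
    n_loops = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, got {line!r}")
            a, b = parts[0], parts[1]
            if a == b:
                n_loops += 1
                continue
            g.add_edge(a, b)
    if n_loops:
        log.info("read_edge_list: dropped %d self-loop(s)", n_loops)
    return g


def write_edge_list(g: nx.Graph, path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in g.edges()):
            fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# Cell matrices (MTX triplet + metadata TSV)
# ---------------------------------------------------------------------------

def write_cell_matrix(cm: CellMatrix, mtx_path, meta_path, genes_path) -> None:
    scipy.io.mmwrite(str(mtx_path), scipy.sparse.csr_matrix(cm.counts))
    pd.DataFrame(
        {
            "cell_id": cm.cell_ids,
            "cluster": cm.cluster,
            "condition": cm.condition,
            "mito_fraction": cm.mito_fraction,
        }
    ).to_csv(meta_path, sep="\t", index=False)
    Path(genes_path).write_text("\n".join(cm.gene_ids) + "\n")


def read_cell_matrix(mtx_path, meta_path, genes_path) -> CellMatrix:
    counts = scipy.io.mmread(str(mtx_path)).toarray().astype(np.int64)
    meta = pd.read_csv(meta_path, sep="\t", dtype={"cell_id": str, "cluster": str})
    gene_ids = [ln for ln in Path(genes_path).read_text().splitlines() if ln]
    return CellMatrix(
        counts=counts,
        cell_ids=list(meta["cell_id"]),
        gene_ids=gene_ids,
        cluster=meta["cluster"].to_numpy(),
        condition=meta["condition"].to_numpy(),
        mito_fraction=meta["mito_fraction"].to_numpy(),
    )


# ---------------------------------------------------------------------------
# Misc
# ---------------------------------------------------------------------------

def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def write_newick(tree, path, precision: int = 6) -> None:
    """Serialize a SampleTree to Newick with the given branch-length precision."""
    Path(path).write_text(tree.to_newick(precision=precision) + "\n")


def read_newick(path):
    from .trees import SampleTree

    return SampleTree.from_newick(Path(path).read_text().strip())
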