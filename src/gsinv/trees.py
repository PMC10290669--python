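"""Unrooted sample trees with branch lengths, plus Newick round-trip support."""
from __future__ import annotations

import io
from dataclasses import dataclass, field

import networkx as nx
from Bio import Phylo


@dataclass
class SampleTree:
    """A fully resolved unrooted tree over sample leaves.

    ``graph`` is an undirected tree whose leaf nodes are sample IDs (strings)
    and whose internal nodes are opaque; every edge carries a non-negative
    ``length`` attribute. ``raw_lengths`` preserves pre-clamping neighbor
    joining estimates for diagnostics.
    """

    graph: nx.Graph
    raw_lengths: dict = field(default_factory=dict)

    @property
    def leaves(self) -> list[str]:
        return sorted(n for n in self.graph.nodes if self.graph.degree(n) == 1)

    @property
    def total_branch_length(self) -> float:
        return float(sum(d["length"] for _, _, d in self.graph.edges(data=True)))

    def leaf_distance(self, a: str, b: str) -> float:
        return float(nx.shortest_path_length(self.graph, a, b, weight="length"))

    def distance_matrix(self):
        """All leaf-to-leaf path lengths as a nested dict."""
        leaves = self.leaves
        return {a: {b: (0.0 if a == b else self.leaf_distance(a, b)) for b in leaves}
                for a in leaves}

    def is_fully_resolved(self) -> bool:
        degs = [self.graph.degree(n) for n in self.graph.nodes
                if self.graph.degree(n) > 1]
        return all(d == 3 for d in degs)

    # -- Newick ----------------------------------------------------------------
    def to_newick(self, precision: int = 6) -> str:
        """Newick string rooted (for serialization only) at an internal node."""
        internal = [n for n in self.graph.nodes if self.graph.degree(n) > 1]
        root = internal[0] if internal else next(iter(self.graph.nodes))

        def render(node, parent):
            children = [n for n in self.graph.neighbors(node) if n != parent]
            if not children:
                return str(node)
            inner = ",".join(
                f"{render(c, node)}:{self.graph[node][c]['length']:.{precision}f}"
                for c in children
            )
            return f"({inner})"

        if self.graph.number_of_nodes() == 1:
            return f"{root};"
        return f"{render(root, None)};"

    @classmethod
    def from_newick(cls, newick: str) -> "SampleTree":
        phylo = Phylo.read(io.StringIO(newick), "newick")
        g = nx.Graph()
        counter = [0]

        def label(clade):
            if clade.name:
                return clade.name
            counter[0] += 1
            return f"_internal{counter[0]}"

        def walk(clade, name):
            for child in clade.clades:
                cname = label(child)
                g.add_edge(name, cname,
                           length=float(child.branch_length or 0.0))
                walk(child, cname)

        root_name = label(phylo.root)
        g.add_node(root_name)
        walk(phylo.root, root_name)
        return cls(g)
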