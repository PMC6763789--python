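"""Global directed pathway network (GDPN) construction.

Per-pathway directed gene graphs are merged into one global directed graph.
Because a gene is topologically important when it *influences* many other
genes — the mirror image of the PageRank notion where a page is important
when many pages point at it — every gene–gene edge is reversed before the
walk.  A virtual node is then linked to and from every gene so the transition
matrix has no dangling rows and probability mass cannot leak; walking on the
closed network is guaranteed to converge.

The transition matrix M is row-stochastic: each row of the (unweighted)
adjacency matrix is divided by its row sum, i.e. a uniform step over
out-neighbours.
"""

from __future__ import annotations

from collections import namedtuple
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse

from .io import VIRTUAL_NODE, PathwayGraphSet, write_json


@dataclass
class GDPN:
    """Closed global directed pathway network.

    ``node_ids`` lists gene IDs (sorted) with the virtual node last, fixing
    the row/column order of ``transition``.  ``edges`` holds the gene–gene
    edges *after* reversal; virtual-node links are implicit (every gene is
    bidirectionally connected to the virtual node).  ``provenance`` maps each
    reversed gene–gene edge to the set of pathway IDs that contributed it.
    """

    node_ids: list[str]
    edges: frozenset[tuple[str, str]]
    transition: sparse.csr_matrix
    provenance: dict[tuple[str, str], frozenset[str]]

    def __post_init__(self) -> None:
        n = len(self.node_ids)
        if self.transition.shape != (n, n):
            raise ValueError("transition shape does not match node list")
        rows = np.asarray(self.transition.sum(axis=1)).ravel()
        if not np.allclose(rows, 1.0, atol=1e-12):
            raise ValueError("transition rows must sum to 1")

    @property
    def gene_ids(self) -> list[str]:
        return self.node_ids[:-1]

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def virtual_index(self) -> int:
        return len(self.node_ids) - 1

    def index_of(self, node_id: str) -> int:
        return self._index[node_id]

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._index

    @property
    def _index(self) -> dict[str, int]:
        idx = getattr(self, "_index_cache", None)
        if idx is None:
            idx = {n: i for i, n in enumerate(self.node_ids)}
            object.__setattr__(self, "_index_cache", idx)
        return idx


def merge_pathways(pathways: PathwayGraphSet) -> nx.DiGraph:
    """Union of all pathway graphs; self-loops dropped, duplicates collapsed.

    Each surviving edge carries a ``pathways`` attribute with the set of
    contributing pathway IDs.
    """
    if len(pathways) == 0:
        raise ValueError("empty pathway set")
    g = nx.DiGraph()
    for p in pathways.pathways:
        g.add_nodes_from(p.genes())
        for u, v in p.edges:
            if u == v:
                continue  # walks are defined on loop-free transitions
            if g.has_edge(u, v):
                g[u][v]["pathways"].add(p.pathway_id)
            else:
                g.add_edge(u, v, pathways={p.pathway_id})
    return g


def close_and_reverse(graph: nx.DiGraph) -> GDPN:
    """Reverse all gene–gene edges, close with the virtual node, normalise.

    Raises if the graph already contains the virtual node: a GDPN cannot be
    re-closed.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if VIRTUAL_NODE in graph:
        raise ValueError("graph already closed: re-closing a GDPN is not allowed")
    genes = sorted(graph.nodes)
    reversed_edges = {}
    for u, v, data in graph.edges(data=True):
        reversed_edges[(v, u)] = frozenset(data.get("pathways", frozenset()))
    return _assemble(genes, reversed_edges)


def _assemble(
    genes: list[str], reversed_edges: dict[tuple[str, str], frozenset[str]]
) -> GDPN:
    node_ids = list(genes) + [VIRTUAL_NODE]
    index = {n: i for i, n in enumerate(node_ids)}
    vi = index[VIRTUAL_NODE]
    rows, cols = [], []
    for (u, v) in reversed_edges:
        rows.append(index[u])
        cols.append(index[v])
    for g in genes:
        gi = index[g]
        rows.extend([gi, vi])
        cols.extend([vi, gi])
    data = np.ones(len(rows))
    adj = sparse.csr_matrix(
        (data, (rows, cols)), shape=(len(node_ids), len(node_ids))
    )
    adj.data[:] = 1.0  # collapse any accidental parallel entries
    out_deg = np.asarray(adj.sum(axis=1)).ravel()
    inv = sparse.diags(1.0 / out_deg)
    transition = (inv @ adj).tocsr()
    return GDPN(
        node_ids=node_ids,
        edges=frozenset(reversed_edges),
        transition=transition,
        provenance=dict(reversed_edges),
    )


def build_gdpn(pathways: PathwayGraphSet) -> GDPN:
    """Merge, reverse and close in one step."""
    return close_and_reverse(merge_pathways(pathways))


def remove_genes(gdpn: GDPN, genes: set[str]) -> GDPN:
    """Rebuild the GDPN with the given gene nodes deleted."""
    keep = [g for g in gdpn.gene_ids if g not in genes]
    if not keep:
        raise ValueError("gene removal would empty the GDPN")
    edges = {
        e: prov
        for e, prov in gdpn.provenance.items()
        if e[0] not in genes and e[1] not in genes
    }
    return _assemble(keep, edges)


PowerLawFit = namedtuple("PowerLawFit", ["r2", "slope", "intercept", "n_points"])


def degree_powerlaw_r2(gdpn: GDPN, mode: str = "total") -> PowerLawFit:
    """R² of a log–log OLS fit to the degree distribution.

    Degrees count gene–gene edges only (the virtual-node closure is an
    algorithmic device, not biology).  Ordinary least squares is fit to
    log10(degree) vs log10(frequency); degrees with zero frequency and
    zero-degree nodes are excluded.  A scale-free-like network gives R²
    close to 1; fewer than 3 distinct positive degrees make the fit
    undefined and return NaN.
    """
    if mode not in ("in", "out", "total"):
        raise ValueError("mode must be 'in', 'out' or 'total'")
    counts: dict[str, int] = {g: 0 for g in gdpn.gene_ids}
    for u, v in gdpn.edges:
        if mode in ("out", "total"):
            counts[u] += 1
        if mode in ("in", "total"):
            counts[v] += 1
    degrees = np.array([d for d in counts.values() if d > 0])
    if degrees.size == 0:
        return PowerLawFit(float("nan"), float("nan"), float("nan"), 0)
    uniq, freq = np.unique(degrees, return_counts=True)
    if uniq.size < 3:
        return PowerLawFit(float("nan"), float("nan"), float("nan"), int(uniq.size))
    x = np.log10(uniq.astype(float))
    y = np.log10(freq.astype(float))
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return PowerLawFit(float(r2), float(slope), float(intercept), int(uniq.size))


def write_gdpn(gdpn: GDPN, edge_path: str | Path, meta_path: str | Path) -> None:
    """Serialise: reversed gene–gene edge list TSV plus JSON metadata."""
    rows = [
        (u, v, ",".join(sorted(prov)))
        for (u, v), prov in sorted(gdpn.provenance.items())
    ]
    pd.DataFrame(rows, columns=["source", "target", "pathways"]).to_csv(
        edge_path, sep="\t", index=False
    )
    meta = {
        "n_gene_nodes": len(gdpn.gene_ids),
        "n_gene_edges": len(gdpn.edges),
        "degree_r2": {
            mode: degree_powerlaw_r2(gdpn, mode).r2 for mode in ("in", "out", "total")
        },
    }
    write_json(meta, meta_path)


def read_gdpn(edge_path: str | Path) -> GDPN:
    """Load a GDPN serialised by :func:`write_gdpn`.

    The edge list is already reversed, so the closure is reassembled
    directly without reversing again.
    """
    df = pd.read_csv(edge_path, sep="\t", comment="#", dtype=str)
    edges: dict[tuple[str, str], frozenset[str]] = {}
    for u, v, prov in zip(df["source"], df["target"], df["pathways"]):
        prov_set = frozenset(str(prov).split(",")) if pd.notna(prov) and prov else frozenset()
        edges[(str(u), str(v))] = prov_set
    genes = sorted({g for e in edges for g in e})
    return _assemble(genes, edges)
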