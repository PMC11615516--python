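"""Pathway network parsing and the symmetric-normalized graph adjacency.

The gene-gene pathway network (e.g. KEGG connections) is mapped onto the fused
feature space: two fused features are adjacent if their gene symbols are
connected in the network, or if they are the same gene observed in different
modalities. The graph convolution then uses S = D^{-1/2} (A + I) D^{-1/2}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

# beyond this many fused features the adjacency is kept sparse
DENSE_LIMIT = 5000


@dataclass
class PathwayGraph:
    """Simple undirected gene-gene network (no self-loops)."""

    graph: nx.Graph

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def has_edge(self, u: str, v: str) -> bool:
        return self.graph.has_edge(u, v)


@dataclass
class NormalizedAdjacency:
    """S = D^{-1/2} (A + I) D^{-1/2} over an ordered feature index.

    ``matrix`` is dense (ndarray) up to DENSE_LIMIT features, sparse CSR beyond;
    the contract is identical. Isolated features reduce to identity rows.
    """

    feature_index: list[str]
    matrix: np.ndarray | sp.csr_matrix

    @property
    def n(self) -> int:
        return len(self.feature_index)

    def dense(self) -> np.ndarray:
        if sp.issparse(self.matrix):
            return self.matrix.toarray()
        return self.matrix

    def dot(self, H: np.ndarray) -> np.ndarray:
        return self.matrix @ H


def read_edge_list(path: str) -> PathwayGraph:
    """Parse a two-column edge list (TSV; SIF's middle interaction column allowed).

    Duplicate and reversed edges are collapsed; self-edges are dropped with a
    logged count; a line with a single token is an error naming the line.
    """
    g: nx.Graph = nx.Graph()
    n_self = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", "\t").split()
            if len(parts) == 2:
                u, v = parts
            elif len(parts) >= 3:  # SIF: source interaction target(s)
                u, rest = parts[0], parts[2:]
                for v in rest:
                    if u == v:
                        n_self += 1
                        g.add_node(u)
                    else:
                        g.add_edge(u, v)
                continue
            else:
                raise ValueError(f"malformed edge line {lineno} in {path}: {line!r}")
            if u == v:
                n_self += 1
                g.add_node(u)
            else:
                g.add_edge(u, v)
    if n_self:
        logger.info("read_edge_list: dropped %d self-edges", n_self)
    return PathwayGraph(g)


def build_feature_adjacency(
    graph: PathwayGraph,
    feature_meta: list[tuple[str, str]],
) -> np.ndarray | sp.csr_matrix:
    """Binary adjacency over fused features from the gene network.

    ``feature_meta`` is the fused-order list of (modality, gene_symbol).
    Distinct features i != j are adjacent iff their symbols are connected in
    the network, or they carry the same gene symbol (cross-modal tie). Features
    whose symbol has no partner and no network neighbour stay isolated (e.g.
    miRNAs absent from the gene network).
    """
    m = len(feature_meta)
    symbols = [sym for _, sym in feature_meta]
    by_symbol: dict[str, list[int]] = {}
    for i, sym in enumerate(symbols):
        by_symbol.setdefault(sym, []).append(i)

    unmapped = sum(1 for sym in set(symbols) if sym not in graph.nodes)
    if unmapped:
        logger.info("build_feature_adjacency: %d symbols absent from the network", unmapped)

    rows: list[int] = []
    cols: list[int] = []

    def connect(ii: list[int], jj: list[int]) -> None:
        for a in ii:
            for b in jj:
                if a != b:
                    rows.append(a)
                    cols.append(b)

    # network edges between symbols present in the fused space
    for u, v in graph.graph.edges:
        if u in by_symbol and v in by_symbol:
            connect(by_symbol[u], by_symbol[v])
            connect(by_symbol[v], by_symbol[u])
    # same-gene cross-modal ties
    for sym, idx in by_symbol.items():
        if len(idx) > 1:
            connect(idx, idx)

    data = np.ones(len(rows))
    A = sp.coo_matrix((data, (rows, cols)), shape=(m, m)).tocsr()
    A.data[:] = 1.0  # collapse duplicates to binary
    A.sum_duplicates()
    A.data[:] = 1.0
    if m <= DENSE_LIMIT:
        return A.toarray()
    return A


def normalize_adjacency(
    A: np.ndarray | sp.spmatrix, feature_index: list[str] | None = None
) -> NormalizedAdjacency:
    """Symmetric normalization with self-loops: S = D^{-1/2}(A+I)D^{-1/2}."""
    sparse = sp.issparse(A)
    m = A.shape[0]
    if A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if sparse:
        if (abs(A - A.T) > 1e-12).nnz != 0:
            raise ValueError("adjacency must be symmetric")
        if A.diagonal().any():
            raise ValueError("adjacency must have a zero diagonal")
        At = (A + sp.identity(m, format="csr")).tocsr()
        deg = np.asarray(At.sum(axis=1)).ravel()
        dinv = 1.0 / np.sqrt(deg)
        D = sp.diags(dinv)
        S = (D @ At @ D).tocsr()
    else:
        A = np.asarray(A, dtype=float)
        if not np.allclose(A, A.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(A) != 0):
            raise ValueError("adjacency must have a zero diagonal")
        At = A + np.eye(m)
        dinv = 1.0 / np.sqrt(At.sum(axis=1))
        S = At * dinv[:, None] * dinv[None, :]
    if feature_index is None:
        feature_index = [str(i) for i in range(m)]
    if len(feature_index) != m:
        raise ValueError("feature_index length must match adjacency size")
    return NormalizedAdjacency(list(feature_index), S)
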