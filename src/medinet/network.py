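"""Directed functional network: loading, reduction, and diffusion operators.

The network mixes gene and miRNA nodes. All scoring happens on the largest
strongly connected component (SCC), where every node has out-degree >= 1 and
the random-walk-with-restart operator is well defined.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.linalg
import scipy.sparse as sp

from .errors import (
    EmptyNetworkError,
    FormatError,
    ParameterError,
    StructureError,
)

__all__ = [
    "DirectedNetwork",
    "TransitionMatrix",
    "DiffusionOperator",
    "load_network",
    "largest_scc",
    "row_normalize",
    "insulated_diffusion",
    "is_mirna_id",
]

#: identifiers that look like a miRNA (miR-375, mmu-let-7a, MIR21, ...)
_MIRNA_RE = re.compile(r"^(?:mmu-|hsa-)?(?:mir|let)[-0-9]", re.IGNORECASE)


def is_mirna_id(node_id: str) -> bool:
    """Classify a feature id as miRNA by its naming convention."""
    return bool(_MIRNA_RE.match(node_id.strip()))


@dataclass(frozen=True)
class DirectedNetwork:
    """Immutable directed graph over gene/miRNA feature ids.

    Node indices are 0-based, dense, and ordered lexicographically by id;
    they are stable for the lifetime of the object.
    """

    nodes: tuple[str, ...]
    edges: tuple[tuple[int, int, str], ...]
    node_kind: Mapping[str, str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.node_kind is None:
            kinds = {n: ("mirna" if is_mirna_id(n) else "gene") for n in self.nodes}
            object.__setattr__(self, "node_kind", kinds)
        for i, j, _ in self.edges:
            if i == j:
                raise StructureError(f"self-edge on node {self.nodes[i]!r}")
        # case-insensitive id -> index lookup
        object.__setattr__(
            self, "_index", {n.strip().casefold(): k for k, n in enumerate(self.nodes)}
        )

    # -- basic accessors ---------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def index_of(self, node_id: str) -> int | None:
        """Index of ``node_id`` (case-insensitive, trimmed), or None."""
        return self._index.get(node_id.strip().casefold())

    def __contains__(self, node_id: str) -> bool:
        return self.index_of(node_id) is not None

    def gene_indices(self) -> np.ndarray:
        return np.array(
            [k for k, n in enumerate(self.nodes) if self.node_kind[n] == "gene"],
            dtype=int,
        )

    def mirna_indices(self) -> np.ndarray:
        return np.array(
            [k for k, n in enumerate(self.nodes) if self.node_kind[n] == "mirna"],
            dtype=int,
        )

    # -- structure ---------------------------------------------------------
    def adjacency(self) -> sp.csr_matrix:
        """Binary adjacency matrix A[i, j] = 1 iff edge i->j."""
        n = self.n_nodes
        if not self.edges:
            return sp.csr_matrix((n, n))
        rows = [e[0] for e in self.edges]
        cols = [e[1] for e in self.edges]
        return sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))

    def reverse(self) -> "DirectedNetwork":
        """Edge-reversed copy (same nodes, same indices)."""
        rev = tuple((j, i, t) for i, j, t in self.edges)
        return DirectedNetwork(self.nodes, rev, self.node_kind)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(
            (self.nodes[i], self.nodes[j], {"type": t}) for i, j, t in self.edges
        )
        return g

    @classmethod
    def from_edge_list(
        cls,
        pairs: Iterable[tuple[str, str] | tuple[str, str, str]],
        node_kind: Mapping[str, str] | None = None,
    ) -> "DirectedNetwork":
        """Build a network from (source, target[, type]) id pairs.

        Self-edges are dropped and duplicate (source, target) pairs collapsed;
        nodes are ordered lexicographically.
        """
        cleaned: dict[tuple[str, str], str] = {}
        names: set[str] = set()
        for row in pairs:
            s, t = row[0].strip(), row[1].strip()
            typ = row[2] if len(row) > 2 else ""
            if not s or not t:
                raise FormatError("empty node id in edge list")
            names.update((s, t))
            if s == t:
                continue
            cleaned.setdefault((s, t), typ)
        nodes = tuple(sorted(names))
        idx = {n: k for k, n in enumerate(nodes)}
        edges = tuple(
            sorted((idx[s], idx[t], typ) for (s, t), typ in cleaned.items())
        )
        return cls(nodes, edges, node_kind)


REQUIRED_COLUMNS = ("source", "target", "directed", "type")


def load_network(edge_table: str | Path, expand_undirected: bool = True) -> DirectedNetwork:
    """Load a directed network from a TSV edge table.

    The table must have columns ``source, target, directed, type`` with
    ``directed`` in {0, 1}. Rows flagged undirected contribute both i->j and
    j->i. Self-edges are dropped and duplicate pairs collapsed.
    """
    df = pd.read_csv(edge_table, sep="\t", dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"edge table is missing required column {col!r}")
    if len(df) == 0:
        raise EmptyNetworkError(f"edge table {edge_table} contains no rows")

    pairs: list[tuple[str, str, str]] = []
    for s, t, d, typ in df[list(REQUIRED_COLUMNS)].itertuples(index=False):
        d = str(d).strip()
        if d not in ("0", "1"):
            raise FormatError(f"directed flag must be 0 or 1, got {d!r}")
        pairs.append((s, t, typ))
        if d == "0" and expand_undirected:
            pairs.append((t, s, typ))
    net = DirectedNetwork.from_edge_list(pairs)
    if net.n_nodes == 0:
        raise EmptyNetworkError(f"edge table {edge_table} yields an empty network")
    return net


def largest_scc(net: DirectedNetwork) -> DirectedNetwork:
    """Induced subgraph on the largest strongly connected component.

    Size ties are broken by keeping the component whose lexicographically
    smallest node id is smallest.
    """
    if net.n_nodes == 0:
        raise EmptyNetworkError("cannot reduce an empty network")
    g = net.to_networkx()
    components = [sorted(c) for c in nx.strongly_connected_components(g)]
    max_size = max(len(c) for c in components)
    best = min((c for c in components if len(c) == max_size), key=lambda c: c[0])
    keep = set(best)
    pairs = [
        (net.nodes[i], net.nodes[j], t)
        for i, j, t in net.edges
        if net.nodes[i] in keep and net.nodes[j] in keep
    ]
    sub_nodes = tuple(sorted(keep))
    if not pairs:
        return DirectedNetwork(sub_nodes, (), {n: net.node_kind[n] for n in sub_nodes})
    sub = DirectedNetwork.from_edge_list(pairs)
    return DirectedNetwork(
        sub.nodes, sub.edges, {n: net.node_kind[n] for n in sub.nodes}
    )


@dataclass(frozen=True)
class TransitionMatrix:
    """Stochastic transition matrix over the nodes of a network."""

    W: sp.csr_matrix
    normalization: str  # {"row_stochastic", "column_stochastic"}
    nodes: tuple[str, ...]

    @property
    def n(self) -> int:
        return self.W.shape[0]


def row_normalize(
    net: DirectedNetwork, normalization: str = "row_stochastic"
) -> TransitionMatrix:
    """Degree-normalized transition matrix: W[i, j] = 1/outdeg(i) per edge i->j.

    ``column_stochastic`` normalizes by in-degree of the target instead (the
    convention is a configuration switch; row-stochastic is the default).
    """
    if normalization not in ("row_stochastic", "column_stochastic"):
        raise ParameterError(f"unknown normalization {normalization!r}")
    a = net.adjacency()
    if normalization == "row_stochastic":
        deg = np.asarray(a.sum(axis=1)).ravel()
        label = "out-degree"
    else:
        deg = np.asarray(a.sum(axis=0)).ravel()
        label = "in-degree"
    zero = np.nonzero(deg == 0)[0]
    if zero.size:
        raise StructureError(
            f"node {net.nodes[zero[0]]!r} has {label} 0; reduce to the largest SCC first"
        )
    if normalization == "row_stochastic":
        w = sp.diags(1.0 / deg) @ a
    else:
        w = a @ sp.diags(1.0 / deg)
    return TransitionMatrix(sp.csr_matrix(w), normalization, net.nodes)


@dataclass(frozen=True)
class DiffusionOperator:
    """Insulated diffusion kernel F = beta * (I - (1-beta) W)^-1."""

    F: np.ndarray
    beta: float
    nodes: tuple[str, ...]

    @property
    def n(self) -> int:
        return self.F.shape[0]

    def rows_mean(self, indices: Sequence[int]) -> np.ndarray:
        """Mean of the rows indexed by ``indices`` (a stochastic vector)."""
        idx = np.asarray(list(indices), dtype=int)
        if idx.size == 0:
            raise ParameterError("rows_mean requires at least one index")
        return self.F[idx].mean(axis=0)


#: above this many nodes the closed-form dense solve is replaced by the
#: power-series iteration (memory, not accuracy, is the concern)
DENSE_CUTOFF = 3000


def insulated_diffusion(
    W: TransitionMatrix, beta: float, dense_cutoff: int = DENSE_CUTOFF
) -> DiffusionOperator:
    """Closed-form random-walk-with-restart operator over a stochastic W.

    F = beta * (I - (1-beta) W)^-1. Rows of F sum to 1 (for row-stochastic W)
    and diagonal entries are >= beta.
    """
    if not (0.0 < beta <= 1.0):
        raise ParameterError(f"beta must lie in (0, 1], got {beta}")
    n = W.n
    dense_w = np.asarray(W.W.todense())
    if n <= dense_cutoff:
        a = np.eye(n) - (1.0 - beta) * dense_w
        try:
            f = beta * scipy.linalg.solve(a, np.eye(n))
        except scipy.linalg.LinAlgError as exc:  # pragma: no cover - unreachable for beta>0
            raise StructureError(f"diffusion system is singular: {exc}") from exc
    else:
        # geometric series beta * sum_k (1-beta)^k W^k, converges for beta > 0
        term = beta * np.eye(n)
        f = term.copy()
        for _ in range(10_000):
            term = (1.0 - beta) * (term @ dense_w)
            f += term
            if np.abs(term).max() < 1e-14:
                break
    return DiffusionOperator(f, beta, W.nodes)
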