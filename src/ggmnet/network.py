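"""Network assembly, clustering-coefficient statistics and Markov-cluster
(MCL) module detection.

Modules are detected with MCL: the unweighted adjacency matrix (signs
ignored) with unit self-loops is column-normalized into a random-walk
matrix, then expansion (matrix power) and inflation (elementwise power with
column renormalization) alternate until the matrix stops changing.  Rows of
the limit matrix with positive diagonal mass are attractors; every node
joins the cluster of the attractor system it flows to.  Modules below the
minimum size are set aside, and the rest are numbered 1, 2, ... by
descending size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd
import networkx as nx

logger = logging.getLogger(__name__)


@dataclass
class NetworkStats:
    n_nodes: int
    n_edges: int
    clustering_coefficient: float
    random_expected_c: float


@dataclass
class MCLParams:
    """MCL controls.  Inflation 1.5 is the published setting; the pruning
    bounds stand in for the mcl binary's "scheme" resource presets."""

    inflation: float = 1.5
    expansion: int = 2
    prune_threshold: float = 1e-6
    max_per_column: int = 1500
    convergence_tol: float = 1e-8
    max_iterations: int = 200
    min_module_size: int = 5

    def __post_init__(self) -> None:
        if self.inflation <= 1:
            raise ValueError("inflation must exceed 1")
        if self.expansion < 2:
            raise ValueError("expansion must be >= 2")
        for v in (self.prune_threshold, self.convergence_tol):
            if v <= 0:
                raise ValueError("tolerances must be positive")


@dataclass
class ModuleAssignment:
    """Gene -> module id for retained modules (ids 1.. by descending size),
    plus the genes relegated to below-minimum-size modules."""

    assignments: dict[str, int]
    small_module_genes: set[str]
    module_sizes: dict[int, int]

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)

    def genes_in_module(self, module_id: int) -> set[str]:
        return {g for g, m in self.assignments.items() if m == module_id}

    def to_frame(self) -> pd.DataFrame:
        rows = [{"gene": g, "module_id": m} for g, m in self.assignments.items()]
        rows += [{"gene": g, "module_id": 0} for g in self.small_module_genes]
        frame = pd.DataFrame(rows, columns=["gene", "module_id"])
        return frame.sort_values(["module_id", "gene"]).reset_index(drop=True)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ModuleAssignment":
        ass = {
            str(r.gene): int(r.module_id)
            for r in frame.itertuples()
            if int(r.module_id) > 0
        }
        small = {str(r.gene) for r in frame.itertuples() if int(r.module_id) == 0}
        sizes: dict[int, int] = {}
        for m in ass.values():
            sizes[m] = sizes.get(m, 0) + 1
        return cls(ass, small, sizes)


def build_network(edges: pd.DataFrame) -> nx.Graph:
    """Build an undirected signed network from an edge table with columns
    gene_a, gene_b and optionally sign, pcor, pcc.  Duplicate rows (either
    orientation) collapse to one edge; self-loops are an error."""
    net = nx.Graph()
    for row in edges.itertuples(index=False):
        a, b = str(row.gene_a), str(row.gene_b)
        if a == b:
            raise ValueError(f"self-loop on gene {a!r}")
        attrs = {
            key: getattr(row, key)
            for key in ("sign", "pcor", "pcc")
            if hasattr(row, key)
        }
        net.add_edge(a, b, **attrs)
    return net


def clustering_coefficient(net: nx.Graph) -> float:
    """Global transitivity: 3 x triangles / connected triples (signs
    ignored); 0 when the graph has no connected triple."""
    if net.number_of_nodes() < 3:
        raise ValueError("clustering coefficient needs at least 3 nodes")
    return float(nx.transitivity(net))


def random_expected_clustering(n_nodes: int, n_edges: int) -> float:
    """Expected clustering coefficient of an Erdos-Renyi random graph of the
    same size: the edge probability 2E / (N(N-1))."""
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    max_edges = n_nodes * (n_nodes - 1) // 2
    if n_edges > max_edges:
        raise ValueError(f"{n_edges} edges exceed the {max_edges} possible")
    return 2.0 * n_edges / (n_nodes * (n_nodes - 1))


def network_stats(net: nx.Graph) -> NetworkStats:
    n, e = net.number_of_nodes(), net.number_of_edges()
    return NetworkStats(
        n_nodes=n,
        n_edges=e,
        clustering_coefficient=clustering_coefficient(net),
        random_expected_c=random_expected_clustering(n, e),
    )


def _normalize_columns(M: np.ndarray) -> np.ndarray:
    sums = M.sum(axis=0)
    sums[sums == 0] = 1.0
    return M / sums


def mcl_iterate(M: np.ndarray, params: MCLParams) -> Iterator[np.ndarray]:
    """Yield the column-stochastic MCL matrix after each
    expansion/inflation/pruning step, until convergence or the iteration cap."""
    for _ in range(params.max_iterations):
        new = np.linalg.matrix_power(M, params.expansion)
        new = new ** params.inflation
        new[new < params.prune_threshold] = 0.0
        k = params.max_per_column
        if k < new.shape[0]:
            # keep only the k largest entries of each column
            drop = np.argpartition(new, -k, axis=0)[:-k]
            np.put_along_axis(new, drop, 0.0, axis=0)
        new = _normalize_columns(new)
        delta = float(np.max(np.abs(new - M)))
        M = new
        yield M
        if delta < params.convergence_tol:
            return
    logger.warning(
        "MCL did not converge within %d iterations; using current matrix",
        params.max_iterations,
    )


def _clusters_from_limit(M: np.ndarray, eps: float) -> list[set[int]]:
    """Read clusters from the MCL limit matrix.

    Attractors are rows with positive diagonal mass.  Attractors connected
    through the limit matrix form one attractor system; every column joins
    the system(s) of the attractors it flows to.
    """
    k = M.shape[0]
    attractors = [i for i in range(k) if M[i, i] > eps]
    if not attractors:  # non-converged fallback: strongest row per column
        attractors = list(set(int(np.argmax(M[:, j])) for j in range(k)))
    # union attractors that appear in each other's support
    parent = {a: a for a in attractors}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[rx] = ry

    aset = set(attractors)
    for a in attractors:
        for b in attractors:
            if a < b and (M[a, b] > eps or M[b, a] > eps):
                union(a, b)

    systems: dict[int, set[int]] = {}
    for a in attractors:
        systems.setdefault(find(a), set()).add(a)
    clusters = {root: set(members) for root, members in systems.items()}
    multi: dict[int, list[int]] = {}
    for j in range(k):
        roots = {find(i) for i in attractors if M[i, j] > eps}
        if not roots:
            roots = {find(int(max(aset, key=lambda i: M[i, j])))}
        for r in roots:
            clusters[r].add(j)
        if len(roots) > 1:
            multi[j] = sorted(roots)
    # overlapping nodes -> the larger cluster (tie: the one that will get
    # the smaller module id, i.e. smaller member indices)
    for j, roots in multi.items():
        best = max(
            roots, key=lambda r: (len(clusters[r]), [-m for m in sorted(clusters[r])])
        )
        for r in roots:
            if r != best:
                clusters[r].discard(j)
    return [c for c in clusters.values() if c]


def mcl_cluster(net: nx.Graph, params: MCLParams | None = None) -> ModuleAssignment:
    """Cluster the network with MCL and return size-filtered, size-ordered
    modules.  Edge signs and weights are ignored: clustering uses topology
    only."""
    if params is None:
        params = MCLParams()
    if net.number_of_nodes() == 0:
        raise ValueError("cannot cluster an empty network")
    nodes = sorted(net.nodes)
    A = nx.to_numpy_array(net, nodelist=nodes, weight=None)
    np.fill_diagonal(A, 1.0)
    M = _normalize_columns(A)
    for M in mcl_iterate(M, params):
        pass
    clusters_idx = _clusters_from_limit(M, params.prune_threshold)
    clusters = [sorted(nodes[i] for i in c) for c in clusters_idx]

    # number by descending size, ties by smallest member gene id
    clusters.sort(key=lambda c: (-len(c), c[0]))
    assignments: dict[str, int] = {}
    small: set[str] = set()
    sizes: dict[int, int] = {}
    next_id = 1
    for members in clusters:
        if len(members) >= params.min_module_size:
            for g in members:
                assignments[g] = next_id
            sizes[next_id] = len(members)
            next_id += 1
        else:
            small.update(members)
    logger.info(
        "MCL: %d modules >= %d genes (%d genes), %d genes in small modules",
        len(sizes), params.min_module_size, len(assignments), len(small),
    )
    return ModuleAssignment(assignments, small, sizes)


def write_modules(modules: ModuleAssignment, path) -> None:
    modules.to_frame().to_csv(path, sep="\t", index=False)


def read_modules(path) -> ModuleAssignment:
    return ModuleAssignment.from_frame(pd.read_csv(path, sep="\t"))
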