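"""Directed motif census and empirical significance testing.

The stabilized SORN connectivity is analyzed the way motif-detection tools
such as Fanmod do: binarize the weight matrix, count weakly-connected
induced subgraphs on 3 or 4 nodes grouped by directed-graph isomorphism
class, and compare each class count against an ensemble of random digraphs
with the same numbers of nodes and edges.  The empirical p-value of a motif
is the fraction of random networks in which it occurs *strictly more often*
than in the observed network, so p ranges over [0, 1] and small p means the
motif is over-represented.

Isomorphism classes are named by a canonical code: the adjacency matrix of
the k-node subgraph is flattened (off-diagonal entries, row-major) into a
bit string, and the minimum value of that bit string over all k! node
permutations is the class code, written as ``"M<k>-<code>"``.  For k <= 4
this brute-force canonicalization is exact and cheap.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import networkx as nx
import numpy as np
import scipy.sparse as sp

__all__ = [
    "MotifReport", "binarize", "census", "null_ensemble", "motif_pvalues",
    "bidirectional_fraction", "canonical_label", "label_to_adjacency",
    "is_feedforward", "motif_name",
]

DEFAULT_WEIGHT_THRESHOLD = 0.01


# -- canonical isomorphism labels -----------------------------------------

def _pair_index(k: int) -> list[tuple[int, int]]:
    return [(i, j) for i in range(k) for j in range(k) if i != j]


@lru_cache(maxsize=None)
def _perm_maps(k: int) -> tuple:
    """For each permutation of k nodes, the bit-position remapping of the
    off-diagonal adjacency encoding."""
    pairs = _pair_index(k)
    pos = {p: b for b, p in enumerate(pairs)}
    maps = []
    for perm in itertools.permutations(range(k)):
        maps.append(tuple(pos[(perm[i], perm[j])] for (i, j) in pairs))
    return tuple(maps)


@lru_cache(maxsize=None)
def _canon_table(k: int) -> np.ndarray:
    """code -> canonical code, for all 2^(k(k-1)) directed k-node graphs."""
    nbits = k * (k - 1)
    maps = _perm_maps(k)
    table = np.empty(2 ** nbits, dtype=np.int64)
    for code in range(2 ** nbits):
        bits = [(code >> b) & 1 for b in range(nbits)]
        best = code
        for m in maps:
            c = 0
            for b, target in enumerate(m):
                if bits[b]:
                    c |= 1 << target
            if c < best:
                best = c
        table[code] = best
    return table


def _subgraph_code(adj: np.ndarray) -> int:
    k = adj.shape[0]
    code = 0
    for b, (i, j) in enumerate(_pair_index(k)):
        if adj[i, j]:
            code |= 1 << b
    return code


def canonical_label(adj: np.ndarray) -> str:
    """Canonical isomorphism-class label of a small directed graph given
    as a boolean adjacency matrix ``adj[i, j] = edge i -> j``."""
    k = adj.shape[0]
    code = int(_canon_table(k)[_subgraph_code(np.asarray(adj) != 0)])
    return f"M{k}-{code}"


def label_to_adjacency(label: str) -> np.ndarray:
    """Adjacency matrix of the canonical representative of a motif class."""
    head, code = label.split("-")
    k, code = int(head[1:]), int(code)
    adj = np.zeros((k, k), dtype=bool)
    for b, (i, j) in enumerate(_pair_index(k)):
        if (code >> b) & 1:
            adj[i, j] = True
    return adj


def is_feedforward(label: str) -> bool:
    """True if the motif class is purely feed-forward: no reciprocal edge
    and no directed cycle."""
    adj = label_to_adjacency(label)
    if np.any(adj & adj.T):
        return False
    return nx.is_directed_acyclic_graph(nx.from_numpy_array(
        adj.astype(int), create_using=nx.DiGraph))


#: Human-readable names for common 3-node classes, keyed lazily by label.
_NAMED_TRIADS = {
    "021C": "feed-forward chain",
    "021D": "divergent (fan-out)",
    "021U": "convergent (fan-in)",
    "030T": "feed-forward triangle",
    "030C": "directed 3-cycle",
    "102": "reciprocal pair",
}


@lru_cache(maxsize=None)
def _triad_label_map() -> dict:
    """networkx triad-census key -> canonical label (connected types only)."""
    out = {}
    for name in nx.algorithms.triads.TRIAD_NAMES:
        g = nx.triad_graph(name)
        und = nx.Graph(g)
        if und.number_of_edges() == 0 or not nx.is_connected(und):
            continue  # 003, 012, 102 with isolated node etc.
        adj = nx.to_numpy_array(g, nodelist=sorted(g.nodes())) != 0
        out[name] = canonical_label(adj)
    return out


def motif_name(label: str) -> str | None:
    """Conventional name of a motif class, if it has one."""
    for triad, lab in _triad_label_map().items():
        if lab == label:
            return _NAMED_TRIADS.get(triad, triad)
    return None


# -- graph construction ---------------------------------------------------

def binarize(w_ee, threshold: float = DEFAULT_WEIGHT_THRESHOLD) -> nx.DiGraph:
    """Directed graph with an edge j -> i wherever ``W^EE_ij`` is
    *strictly* greater than ``threshold``.

    Accepts a dense array, a scipy sparse matrix, or a
    :class:`~sorn.state.NetworkState`.  All neurons appear as nodes even if
    isolated.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    w = getattr(w_ee, "w", w_ee)
    if sp.issparse(w):
        w = np.asarray(w.todense())
    w = np.asarray(w)
    n = w.shape[0]
    g = nx.DiGraph()
    g.add_nodes_from(range(n))
    ii, jj = np.nonzero(w > threshold)
    g.add_edges_from(zip(jj.tolist(), ii.tolist()))  # j -> i
    return g


# -- census ---------------------------------------------------------------

def census(graph: nx.DiGraph, k: int) -> dict[str, int]:
    """Counts of weakly-connected induced ``k``-node subgraphs per
    isomorphism class.  ``k`` must be 3 or 4."""
    if k == 3:
        return _census_triads(graph)
    if k == 4:
        return _census_esu(graph, 4)
    raise ValueError("census supports k in {3, 4} only")


def _census_triads(graph: nx.DiGraph) -> dict[str, int]:
    # exhaustive vectorized enumeration of connected triples; each triple's
    # 6-bit directed code is canonicalized through the k=3 lookup table
    nodes = sorted(graph.nodes())
    index = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    adj = np.zeros((n, n), dtype=np.bool_)
    for u, v in graph.edges():
        adj[index[u], index[v]] = True
    counts = _triad_count_kernel(adj, _canon_table(3))
    return {f"M3-{code}": int(c)
            for code, c in enumerate(counts) if c > 0}


def _triad_count_kernel(adj: np.ndarray, canon: np.ndarray) -> np.ndarray:
    from ._kernels import triad_census_dense
    return triad_census_dense(adj, canon)


def _census_esu(graph: nx.DiGraph, k: int) -> dict[str, int]:
    """ESU enumeration of weakly-connected induced k-node subgraphs."""
    n = graph.number_of_nodes()
    nodes = sorted(graph.nodes())
    index = {v: i for i, v in enumerate(nodes)}
    adj = np.zeros((n, n), dtype=bool)
    for u, v in graph.edges():
        adj[index[u], index[v]] = True
    und = [set(np.flatnonzero(adj[i] | adj[:, i])) for i in range(n)]
    table = _canon_table(k)
    counts: dict[int, int] = {}

    def extend(sub: list[int], ext: set[int], v: int) -> None:
        if len(sub) == k:
            code = 0
            b = 0
            for a in range(k):
                for c in range(k):
                    if a != c:
                        if adj[sub[a], sub[c]]:
                            code |= 1 << b
                        b += 1
            canon = int(table[code])
            counts[canon] = counts.get(canon, 0) + 1
            return
        ext = set(ext)
        while ext:
            w = ext.pop()
            new_ext = ext | {u for u in und[w]
                             if u > v and u not in sub and u not in ext
                             and all(u not in und[s] for s in sub)}
            extend(sub + [w], new_ext, v)

    for v in range(n):
        extend([v], {u for u in und[v] if u > v}, v)
    return {f"M{k}-{code}": c for code, c in sorted(counts.items())}


# -- null model and p-values ----------------------------------------------

def null_ensemble(n_nodes: int, n_edges: int, n_networks: int = 1000,
                  rng: np.random.Generator | None = None) -> list[nx.DiGraph]:
    """Random directed graphs with exactly ``n_edges`` edges placed
    uniformly among the ordered non-self pairs of ``n_nodes`` nodes."""
    if rng is None:
        rng = np.random.default_rng()
    max_edges = n_nodes * (n_nodes - 1)
    if n_edges > max_edges:
        raise ValueError("more edges than ordered pairs")
    graphs = []
    for _ in range(n_networks):
        flat = rng.choice(max_edges, size=n_edges, replace=False)
        src, off = np.divmod(flat, n_nodes - 1)
        dst = off + (off >= src)  # skip the diagonal
        g = nx.DiGraph()
        g.add_nodes_from(range(n_nodes))
        g.add_edges_from(zip(src.tolist(), dst.tolist()))
        graphs.append(g)
    return graphs


@dataclass
class MotifReport:
    """Observed and null statistics for one motif class."""

    motif_class: str
    count_observed: int
    null_counts: list[int]
    p_value: float

    @property
    def name(self) -> str | None:
        return motif_name(self.motif_class)

    @property
    def feedforward(self) -> bool:
        return is_feedforward(self.motif_class)


def motif_pvalues(graph: nx.DiGraph, k: int = 3, n_networks: int = 100,
                  rng: np.random.Generator | None = None
                  ) -> list[MotifReport]:
    """Empirical motif p-values of ``graph`` against a fixed-edge-count
    random ensemble.

    One report per isomorphism class appearing in either the observed
    graph or any null graph; ``p = (#nulls with count > observed) /
    #nulls`` (strict inequality, so ties do not count against the
    observed network).
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("graph must be nonempty")
    observed = census(graph, k)
    nulls = null_ensemble(graph.number_of_nodes(), graph.number_of_edges(),
                          n_networks, rng)
    null_censuses = [census(g, k) for g in nulls]
    classes = set(observed)
    for c in null_censuses:
        classes.update(c)
    reports = []
    for cls in sorted(classes):
        obs = observed.get(cls, 0)
        null_counts = [c.get(cls, 0) for c in null_censuses]
        p = sum(1 for c in null_counts if c > obs) / len(null_counts)
        reports.append(MotifReport(cls, obs, null_counts, p))
    return reports


# -- reciprocal connectivity ----------------------------------------------

def bidirectional_fraction(w_ee) -> float:
    """Fraction of reciprocally connected pairs.

    Counts unordered pairs {i, j} with synapses in both directions, once
    per pair, and divides by ``(N^E)^2`` (the conventional normalization
    for this statistic, not the number of pairs).
    """
    w = getattr(w_ee, "w", w_ee)
    if sp.issparse(w):
        w = np.asarray(w.todense())
    a = np.asarray(w) > 0
    n = a.shape[0]
    return float(np.count_nonzero(a & a.T) / 2 / n ** 2)
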