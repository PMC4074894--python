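"""Synfire pool and ring identification from rasters and weights.

A *pool* (layer) is a set of excitatory neurons with strongly correlated
activity; pools are found as connected components of the thresholded
pairwise-correlation graph.  A *synfire ring* is a cyclic arrangement of
pools in which each pool densely projects onto its successor, so that a
wave of synchronous activity travels around the cycle and re-excites
itself.  Rings are extracted from the pool-level connectivity graph: each
pool is linked to the pool it projects to most densely (if that density
clears a threshold), and the cycles of the resulting successor map are the
rings; maximal non-cyclic successor paths are reported as chains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.stats import skew

from .engine import SpikeRaster
from .motifs import DEFAULT_WEIGHT_THRESHOLD

__all__ = [
    "PoolPartition", "RingStructure", "activity_correlations",
    "cross_correlogram", "detect_pools", "extract_rings",
    "pool_size_stats", "weight_distribution_stats", "analyze_run",
]

DEFAULT_CORR_THRESHOLD = 0.2
DEFAULT_DENSITY_THRESHOLD = 0.5


# -- correlation statistics -----------------------------------------------

def activity_correlations(raster: SpikeRaster | np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of the neurons' binary spike trains.

    Neurons with zero variance (always silent or always active over the
    raster) get correlation 0 against everything, including themselves.
    """
    x = raster.activity if isinstance(raster, SpikeRaster) else raster
    x = np.asarray(x, dtype=np.float64)
    if x.shape[1] < 100:
        raise ValueError("need at least 100 raster steps for correlations")
    varying = x.std(axis=1) > 0
    corr = np.zeros((x.shape[0], x.shape[0]))
    if varying.sum() >= 2:
        sub = np.corrcoef(x[varying])
        corr[np.ix_(varying, varying)] = sub
    elif varying.sum() == 1:
        i = int(np.flatnonzero(varying)[0])
        corr[i, i] = 1.0
    return corr


def cross_correlogram(raster: SpikeRaster | np.ndarray, i: int, j: int,
                      max_lag: int) -> np.ndarray:
    """Counts, per lag ``l`` in ``[-max_lag, max_lag]``, of steps where
    neuron ``i`` spikes at ``t`` and neuron ``j`` spikes at ``t + l``.

    Index ``max_lag + l`` of the returned array holds lag ``l``.
    """
    x = raster.activity if isinstance(raster, SpikeRaster) else raster
    xi = np.asarray(x[i], dtype=np.int64)
    xj = np.asarray(x[j], dtype=np.int64)
    n = xi.size
    if max_lag >= n:
        raise ValueError("max_lag must be smaller than the raster length")
    out = np.zeros(2 * max_lag + 1, dtype=np.int64)
    for lag in range(-max_lag, max_lag + 1):
        if lag >= 0:
            out[max_lag + lag] = int(xi[:n - lag] @ xj[lag:])
        else:
            out[max_lag + lag] = int(xi[-lag:] @ xj[:n + lag])
    return out


# -- pools ----------------------------------------------------------------

@dataclass
class PoolPartition:
    """Partition of the excitatory population into correlated pools."""

    pools: list[np.ndarray]            # sorted neuron indices per pool
    unassigned: np.ndarray             # neurons in no pool
    correlation_threshold: float

    @property
    def n_pools(self) -> int:
        return len(self.pools)

    @property
    def pool_sizes(self) -> list[int]:
        return [len(p) for p in self.pools]

    def pool_of(self, neuron: int) -> int | None:
        for idx, p in enumerate(self.pools):
            if neuron in self._sets[idx]:
                return idx
        return None

    def __post_init__(self) -> None:
        self._sets = [set(p.tolist()) for p in self.pools]

    def display_order(self) -> np.ndarray:
        """Neuron ordering that groups pool members together (pools first,
        then unassigned neurons) — the conventional raster display order."""
        parts = [np.asarray(p, dtype=int)
                 for p in [*self.pools, self.unassigned] if len(p)]
        return np.concatenate(parts) if parts else np.array([], dtype=int)


def detect_pools(corr: np.ndarray,
                 threshold: float = DEFAULT_CORR_THRESHOLD) -> PoolPartition:
    """Pools = connected components (of size >= 2) of the graph linking
    neuron pairs whose correlation exceeds ``threshold``."""
    if not 0 < threshold < 1:
        raise ValueError("correlation threshold must lie in (0, 1)")
    corr = np.asarray(corr)
    n = corr.shape[0]
    adj = corr > threshold
    np.fill_diagonal(adj, False)
    n_comp, labels = connected_components(sp.csr_matrix(adj), directed=False)
    pools, unassigned = [], []
    for comp in range(n_comp):
        members = np.flatnonzero(labels == comp)
        if members.size >= 2:
            pools.append(members)
        else:
            unassigned.extend(members.tolist())
    pools.sort(key=lambda p: int(p[0]))
    return PoolPartition(pools=pools,
                         unassigned=np.array(sorted(unassigned), dtype=int),
                         correlation_threshold=threshold)


# -- rings ----------------------------------------------------------------

@dataclass
class RingStructure:
    """Rings (and leftover chains) in the pool-level connectivity graph."""

    rings: list[list[int]]                 # ordered pool indices per ring
    chains: list[list[int]]                # maximal non-cyclic paths
    partition: PoolPartition
    pool_sizes: list[list[int]] = field(default_factory=list)
    inter_pool_weights: list[list[float]] = field(default_factory=list)
    density: np.ndarray = None   # pool-to-pool input-mass fraction matrix

    @property
    def n_rings(self) -> int:
        return len(self.rings)

    def ring_neurons(self, ring_idx: int) -> np.ndarray:
        return np.concatenate(
            [self.partition.pools[p] for p in self.rings[ring_idx]])

    @property
    def neurons_in_rings(self) -> np.ndarray:
        if not self.rings:
            return np.array([], dtype=int)
        return np.concatenate([self.ring_neurons(r)
                               for r in range(self.n_rings)])

    def successor_pool(self, pool_idx: int) -> int | None:
        """The next pool around the ring containing ``pool_idx``."""
        for ring in self.rings:
            if pool_idx in ring:
                return ring[(ring.index(pool_idx) + 1) % len(ring)]
        return None


def extract_rings(w_ee, partition: PoolPartition,
                  weight_threshold: float = DEFAULT_WEIGHT_THRESHOLD,
                  density_threshold: float = DEFAULT_DENSITY_THRESHOLD
                  ) -> RingStructure:
    """Extract synfire rings from the weight matrix given a pool partition.

    The pool-level edge strength A -> B is the average, over neurons of
    B, of the summed synaptic weight received from members of A (weights
    at or below ``weight_threshold`` are ignored).  Because synaptic
    scaling normalizes every neuron's total excitatory input to one, this
    is the fraction of B's excitatory drive supplied by A, independent of
    pool sizes.  An edge exists when that fraction reaches
    ``density_threshold`` (default: A supplies at least half of B's
    input).  Each pool follows its strongest outgoing edge; the cycles of
    that successor map are the rings, and remaining maximal successor
    paths are chains.
    """
    if partition.n_pools == 0:
        return RingStructure([], [], partition, density=np.zeros((0, 0)))
    w = getattr(w_ee, "w", w_ee)
    if sp.issparse(w):
        w = np.asarray(w.todense())
    w = np.where(np.asarray(w) > weight_threshold, w, 0.0)
    # express every neuron's input as fractions of its total surviving
    # input (a no-op after synaptic scaling, up to the threshold mask)
    sums = w.sum(axis=1, keepdims=True)
    w = np.divide(w, sums, out=np.zeros_like(w), where=sums > 0)
    np_pools = partition.n_pools

    density = np.zeros((np_pools, np_pools))   # input-mass fractions
    mean_w = np.zeros((np_pools, np_pools))
    for a in range(np_pools):
        for c in range(np_pools):
            if a == c:
                continue
            # synapses from pool a onto pool c: rows = targets, cols = sources
            block = w[np.ix_(partition.pools[c], partition.pools[a])]
            density[a, c] = block.sum(axis=1).mean()
            mean_w[a, c] = block.mean()

    successor = np.full(np_pools, -1)
    for a in range(np_pools):
        best = int(np.argmax(density[a]))
        if density[a, best] >= density_threshold:
            successor[a] = best

    rings, on_ring = [], np.zeros(np_pools, dtype=bool)
    # cycles of the successor map, discovered from the densest edges first
    order = np.argsort(-np.array([density[a, successor[a]]
                                  if successor[a] >= 0 else -1.0
                                  for a in range(np_pools)]))
    visited = np.zeros(np_pools, dtype=bool)
    for start in order:
        if visited[start] or successor[start] < 0:
            continue
        path, seen = [], {}
        node = int(start)
        while node >= 0 and node not in seen and not visited[node]:
            seen[node] = len(path)
            path.append(node)
            node = int(successor[node])
        if node >= 0 and node in seen and not visited[node]:
            cycle = path[seen[node]:]
            rings.append(cycle)
            for p in cycle:
                on_ring[p] = True
        for p in path:
            visited[p] = True

    # maximal chains: walk the successor map from pools that no pool points
    # to, stopping when hitting a ring or a dead end
    chains = []
    pointed_at = {int(successor[a]) for a in range(np_pools)
                  if successor[a] >= 0}
    for start in range(np_pools):
        if on_ring[start] or start in pointed_at:
            continue
        path, node = [], int(start)
        while node >= 0 and not on_ring[node] and node not in path:
            path.append(node)
            node = int(successor[node])
        if len(path) >= 2:
            chains.append(path)

    sizes = [[len(partition.pools[p]) for p in ring] for ring in rings]
    weights = [[float(mean_w[ring[k], ring[(k + 1) % len(ring)]])
                for k in range(len(ring))] for ring in rings]
    return RingStructure(rings=rings, chains=chains, partition=partition,
                         pool_sizes=sizes, inter_pool_weights=weights,
                         density=density)


# -- descriptive statistics -----------------------------------------------

def pool_size_stats(runs: list[RingStructure]) -> dict:
    """Pool-size summary over a collection of analyzed runs.

    Returns max/min/SD of all ring-pool sizes, the mean within-ring SD,
    the SD of per-ring mean pool sizes (across-ring variability), and the
    fraction of runs that developed at least two rings.
    """
    if not runs:
        raise ValueError("need at least one run")
    all_sizes, within_sds, ring_means = [], [], []
    multi = 0
    for rs in runs:
        if rs.n_rings >= 2:
            multi += 1
        for sizes in rs.pool_sizes:
            all_sizes.extend(sizes)
            ring_means.append(float(np.mean(sizes)))
            if len(sizes) >= 2:
                within_sds.append(float(np.std(sizes)))
    stats = {
        "n_runs": len(runs),
        "multi_ring_fraction": multi / len(runs),
        "max_pool_size": int(max(all_sizes)) if all_sizes else 0,
        "min_pool_size": int(min(all_sizes)) if all_sizes else 0,
        "pool_size_sd": float(np.std(all_sizes)) if all_sizes else float("nan"),
        "mean_within_ring_sd":
            float(np.mean(within_sds)) if within_sds else float("nan"),
        "across_ring_sd":
            float(np.std(ring_means)) if ring_means else float("nan"),
        "n_pools_mean":
            float(np.mean([r.partition.n_pools for r in runs])),
    }
    return stats


def weight_distribution_stats(w_ee, n_bins: int = 30) -> dict:
    """Shape statistics of the surviving excitatory weight distribution.

    In stabilized networks this distribution is lognormal-like: reported
    here as deciles of log10-weights, skewness on the log scale, the
    max/min dynamic range, and a unimodality check of the log-histogram
    (modes are histogram peaks rising at least 10% of the maximum above
    their surroundings, after 3-bin smoothing).
    """
    w = getattr(w_ee, "w", w_ee)
    if sp.issparse(w):
        w = np.asarray(w.todense())
    vals = np.asarray(w)[np.asarray(w) > 0]
    if vals.size < 10:
        raise ValueError("need at least 10 weights")
    logs = np.log10(vals)
    hist, _ = np.histogram(logs, bins=n_bins)
    smooth = np.convolve(hist, np.ones(3) / 3, mode="same")
    from scipy.signal import find_peaks
    peaks, _ = find_peaks(smooth, prominence=0.1 * smooth.max())
    if smooth.argmax() in (0, len(smooth) - 1):
        peaks = np.append(peaks, smooth.argmax())  # edge maxima count too
    n_modes = max(len(peaks), 1)
    return {
        "n_weights": int(vals.size),
        "log10_deciles": np.percentile(logs, np.arange(0, 101, 10)).tolist(),
        "log_skewness": float(skew(logs)) if np.ptp(logs) > 0 else 0.0,
        "dynamic_range": float(vals.max() / vals.min()),
        "n_modes": int(n_modes),
        "unimodal": bool(n_modes == 1),
    }


# -- convenience pipeline -------------------------------------------------

def analyze_run(record, corr_threshold: float = DEFAULT_CORR_THRESHOLD,
                weight_threshold: float = DEFAULT_WEIGHT_THRESHOLD,
                density_threshold: float = DEFAULT_DENSITY_THRESHOLD
                ) -> RingStructure:
    """Pools + rings of a finished run, from its final raster and weights."""
    corr = activity_correlations(record.final_raster)
    partition = detect_pools(corr, corr_threshold)
    return extract_rings(record.final_state, partition,
                         weight_threshold, density_threshold)
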