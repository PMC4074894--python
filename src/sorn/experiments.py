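"""Perturbation, ablation and sweep experiments, plus planted fixtures.

These scripted experiments probe *why* synfire rings form and stay stable:

* :func:`insert_and_track` plants strong synapses that are inconsistent
  with an existing ring (within one layer, or skipping a layer) and
  watches synaptic scaling plus STDP fluctuations drive them to
  elimination.
* :func:`track_structural_fates` follows every synapse born from
  structural plasticity during the stable phase and records whether it
  lies on the synfire route (pool k -> pool k+1) and how long it lives.
* :func:`ablate` switches off chosen plasticity mechanisms and reports
  whether rings still form and whether the dynamics stay in a healthy
  regime.
* :func:`sweep` runs replicate simulations along one parameter axis
  (target rate, target-rate spread, or network size) and aggregates pool
  statistics.
* :func:`generate_planted_fixture` builds block-cyclic ground-truth
  networks and rasters used to validate the analysis modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import MECHANISMS, full_step
from .engine import RunRecord, SimulationConfig, SpikeRaster, run
from .params import SornParams
from .state import NetworkState
from .synfire import (PoolPartition, RingStructure, activity_correlations,
                      analyze_run, detect_pools, extract_rings,
                      pool_size_stats)

__all__ = [
    "PerturbationSpec", "AblationSpec", "InsertionResult", "FateRecord",
    "AblationResult", "insert_and_track", "track_structural_fates",
    "ablate", "sweep", "generate_planted_fixture", "SWEEP_AXES",
]


# -- perturbation / insertion ---------------------------------------------

PERTURBATION_KINDS = ("within_layer", "skip_layer", "on_route", "off_route")


@dataclass
class PerturbationSpec:
    """How to insert probe synapses relative to an existing ring.

    ``within_layer`` connects two neurons of the same pool, ``skip_layer``
    a pool to the pool two steps ahead, ``on_route`` a pool to its
    successor, and ``off_route`` any pool pair that violates the ring
    order.  Insertions happen one at a time, ``period`` steps apart.
    """

    kind: str = "within_layer"
    weight: float = 0.1
    count: int = 10
    period: int = 500
    track_horizon: int = 10_000

    def __post_init__(self) -> None:
        if self.kind not in PERTURBATION_KINDS:
            raise ValueError(f"kind must be one of {PERTURBATION_KINDS}")
        if self.weight <= 0:
            raise ValueError("weight must be > 0")
        if self.period <= 0 or self.count < 1 or self.track_horizon < 0:
            raise ValueError("period, count, track_horizon must be positive")


@dataclass
class InsertionResult:
    """Weight trajectories of manually inserted synapses."""

    spec: PerturbationSpec
    pairs: list[tuple[int, int]]           # (post, pre)
    birth_steps: list[int]
    trajectories: list[np.ndarray]         # weight per step since birth
    eliminated_step: list[int | None]      # steps after birth, or None

    @property
    def all_eliminated(self) -> bool:
        return all(e is not None for e in self.eliminated_step)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s, (pair, birth, traj, elim) in enumerate(zip(
                self.pairs, self.birth_steps, self.trajectories,
                self.eliminated_step)):
            for k, wv in enumerate(traj):
                rows.append((s, pair[0], pair[1], birth, birth + k,
                             wv, elim))
        return pd.DataFrame(rows, columns=[
            "synapse", "post", "pre", "birth_step", "step", "weight",
            "eliminated_after"])


def _pool_pair_for_kind(rings: RingStructure, kind: str,
                        rng: np.random.Generator) -> tuple[int, int]:
    """Pick (source pool, target pool) for an insertion kind."""
    if rings.n_rings == 0:
        raise ValueError("no synfire ring detected; perturbation undefined")
    ring = max(rings.rings, key=lambda r: sum(
        len(rings.partition.pools[p]) for p in r))
    k = int(rng.integers(len(ring)))
    if kind == "within_layer":
        return ring[k], ring[k]
    if kind == "on_route":
        return ring[k], ring[(k + 1) % len(ring)]
    if kind == "skip_layer":
        return ring[k], ring[(k + 2) % len(ring)]
    # off_route: any ordered pool pair that is not source -> successor
    pools = list(range(rings.partition.n_pools))
    for _ in range(100):
        a = int(rng.choice(pools))
        b = int(rng.choice(pools))
        if a != b and rings.successor_pool(a) != b:
            return a, b
    raise ValueError("could not find an off-route pool pair")


def _sample_unconnected_pair(state: NetworkState, src_pool: np.ndarray,
                             dst_pool: np.ndarray,
                             rng: np.random.Generator) -> tuple[int, int]:
    for _ in range(1000):
        j = int(rng.choice(src_pool))
        i = int(rng.choice(dst_pool))
        if i != j and state.w[i, j] == 0.0:
            return i, j
    raise ValueError("no unconnected pair available between the pools")


def insert_and_track(state: NetworkState, rings: RingStructure,
                     spec: PerturbationSpec, params: SornParams,
                     rng: np.random.Generator,
                     disabled: frozenset[str] = frozenset()
                     ) -> InsertionResult:
    """Insert probe synapses into a stable-phase network and track them.

    The state is advanced in place.  One synapse of strength
    ``spec.weight`` is created every ``spec.period`` steps (``spec.count``
    in total), each recorded for ``spec.track_horizon`` steps after its
    birth or until elimination.  With all plasticity disabled this is a
    control: weights stay constant.
    """
    partition = rings.partition
    pairs: list[tuple[int, int]] = []
    births: list[int] = []
    trajs: list[list[float]] = []
    elim: list[int | None] = []
    total = (spec.count - 1) * spec.period + spec.track_horizon
    t0 = state.t

    for step in range(total + 1):
        if step % spec.period == 0 and len(pairs) < spec.count:
            src_pool, dst_pool = _pool_pair_for_kind(rings, spec.kind, rng)
            i, j = _sample_unconnected_pair(
                state, partition.pools[src_pool], partition.pools[dst_pool],
                rng)
            state.add_ee_synapse(i, j, spec.weight)
            pairs.append((i, j))
            births.append(t0 + step)
            trajs.append([spec.weight])
            elim.append(None)
        if step == total:
            break
        full_step(state, params, rng, disabled=disabled)
        for s, (i, j) in enumerate(pairs):
            if elim[s] is not None or len(trajs[s]) > spec.track_horizon:
                continue
            wv = state.w[i, j]
            trajs[s].append(float(wv))
            if wv == 0.0:
                elim[s] = len(trajs[s]) - 1
    return InsertionResult(
        spec=spec, pairs=pairs, birth_steps=births,
        trajectories=[np.array(t) for t in trajs], eliminated_step=elim)


# -- structural synapse fates ---------------------------------------------

@dataclass
class FateRecord:
    """Life history of one structurally created synapse."""

    post: int
    pre: int
    birth_step: int
    on_route: bool            # pre's pool projects onto post's pool next
    lifetime: int | None      # steps until elimination; None = still alive
    max_weight: float
    trajectory: np.ndarray


def track_structural_fates(state: NetworkState, rings: RingStructure,
                           params: SornParams, rng: np.random.Generator,
                           horizon: int = 20_000,
                           disabled: frozenset[str] = frozenset()
                           ) -> list[FateRecord]:
    """Simulate ``horizon`` steps and follow every structurally added
    synapse.

    A synapse j -> i is *on-route* when j's pool and i's pool are
    consecutive around a detected ring; anything else (including synapses
    touching unpooled neurons) is off-route.
    """
    partition = rings.partition
    alive: dict[tuple[int, int], FateRecord] = {}
    traj: dict[tuple[int, int], list[float]] = {}
    done: list[FateRecord] = []
    t0 = state.t

    for step in range(horizon):
        info = full_step(state, params, rng, disabled=disabled)
        if info.added is not None:
            i, j = info.added
            p_pre = partition.pool_of(j)
            p_post = partition.pool_of(i)
            on_route = (p_pre is not None
                        and rings.successor_pool(p_pre) == p_post
                        and p_post is not None)
            rec = FateRecord(post=i, pre=j, birth_step=t0 + step + 1,
                             on_route=on_route, lifetime=None,
                             max_weight=0.0, trajectory=None)
            alive[(i, j)] = rec
            traj[(i, j)] = []
        dead = []
        for key, rec in alive.items():
            wv = float(state.w[key])
            traj[key].append(wv)
            if wv > rec.max_weight:
                rec.max_weight = wv
            if wv == 0.0:
                rec.lifetime = len(traj[key])
                rec.trajectory = np.array(traj[key])
                done.append(rec)
                dead.append(key)
        for key in dead:
            del alive[key], traj[key]
    for key, rec in alive.items():
        rec.trajectory = np.array(traj[key])
        done.append(rec)
    done.sort(key=lambda r: r.birth_step)
    return done


def fate_summary(fates: list[FateRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "post": f.post, "pre": f.pre, "birth_step": f.birth_step,
        "on_route": f.on_route, "lifetime": f.lifetime,
        "max_weight": f.max_weight} for f in fates])


# -- ablations ------------------------------------------------------------

@dataclass
class AblationSpec:
    """Which plasticity mechanisms to switch off."""

    disabled: frozenset[str]

    def __post_init__(self) -> None:
        self.disabled = frozenset(self.disabled)
        if not self.disabled:
            raise ValueError("ablation requires at least one mechanism")
        unknown = self.disabled - MECHANISMS
        if unknown:
            raise ValueError(f"unknown mechanisms: {sorted(unknown)}")


@dataclass
class AblationResult:
    record: RunRecord
    rings: RingStructure
    healthy: bool              # rate near target, no runaway synchrony
    row_sums_ok: bool          # EE rows still normalized at the end


def healthy_regime(record: RunRecord, window: int | None = None,
                   rate_tol: float = 0.05,
                   synchrony_limit: float = 0.5) -> bool:
    """Operational "healthy regime" check over the trailing window: mean
    excitatory rate within ``rate_tol`` of the target and no step with
    more than ``synchrony_limit`` of the units simultaneously active."""
    if window is None:
        window = min(record.config.stability_window,
                     len(record.mean_rate))
    if window == 0:
        return False
    tail = record.mean_rate[-window:]
    mu = record.params.mu_ip
    return bool(abs(float(tail.mean()) - mu) <= rate_tol
                and float(tail.max()) <= synchrony_limit)


def ablate(params: SornParams, spec: AblationSpec,
           config: SimulationConfig | None = None,
           rng: np.random.Generator | None = None) -> AblationResult:
    """Run the network with some mechanisms disabled and report the
    resulting structure.

    Broken invariants (for example row sums drifting when scaling is off)
    are flagged in the result rather than raised.
    """
    record = run(params, config, disabled=spec.disabled, rng=rng)
    rings = analyze_run(record)
    state = record.final_state
    sums = state.w.sum(axis=1)
    nonempty = state.row_len > 0
    row_sums_ok = bool(np.all(np.abs(sums[nonempty] - 1.0) < 1e-6))
    return AblationResult(record=record, rings=rings,
                          healthy=healthy_regime(record),
                          row_sums_ok=row_sums_ok)


# -- parameter sweeps -----------------------------------------------------

SWEEP_AXES = {
    "mu_ip": (0.025, 0.125),
    "sigma_hip": (0.0, 0.08),
    "n_excitatory": (200, 800),
}


def sweep(params: SornParams, axis: str, values, replicates: int,
          config: SimulationConfig | None = None,
          base_seed: int = 0) -> pd.DataFrame:
    """Replicated runs along one parameter axis with pool statistics.

    Returns one row per (value, replicate) with ring/pool summaries, and
    is reproducible per (setting, replicate): the run seed is derived
    deterministically from ``base_seed``, the axis position and the
    replicate index.
    """
    lo, hi = SWEEP_AXES.get(axis, (None, None))
    if lo is None:
        raise ValueError(f"axis must be one of {sorted(SWEEP_AXES)}")
    rows = []
    for vi, value in enumerate(values):
        if not lo <= value <= hi:
            raise ValueError(f"{axis}={value} outside the studied "
                             f"range [{lo}, {hi}]")
        for rep in range(replicates):
            seed = int(np.random.SeedSequence(
                [base_seed, vi, rep]).generate_state(1)[0] % (2 ** 31))
            if axis == "n_excitatory":
                p = params.replace(n_excitatory=int(value), seed=seed)
            else:
                p = params.replace(**{axis: float(value)}, seed=seed)
            record = run(p, config)
            rings = analyze_run(record)
            stats = pool_size_stats([rings])
            rows.append({
                "axis": axis, "value": value, "replicate": rep,
                "seed": seed, "n_pools": rings.partition.n_pools,
                "n_rings": rings.n_rings,
                "max_pool_size": stats["max_pool_size"],
                "min_pool_size": stats["min_pool_size"],
                "pool_size_sd": stats["pool_size_sd"],
                "multi_ring": rings.n_rings >= 2,
                "stable_step": record.stable_step,
            })
    return pd.DataFrame(rows)


# -- planted fixtures -----------------------------------------------------

def generate_planted_fixture(n_pools: int, pool_sizes, edge_noise: float,
                             cycle: bool, rng: np.random.Generator,
                             raster_steps: int = 500,
                             flip_noise: float | None = None
                             ) -> tuple[np.ndarray, SpikeRaster]:
    """Block-cyclic ground-truth network plus a matching spike raster.

    Consecutive pools are densely connected (each possible synapse from
    pool k onto pool k+1 is present with probability ``1 - edge_noise``);
    every other ordered neuron pair carries a spurious synapse with
    probability ``edge_noise``.  Rows are normalized to sum to one.  With
    ``cycle=True`` the last pool projects back onto the first (a synfire
    ring); otherwise the chain terminates.

    The raster activates pools in sequence, one pool per step, with each
    neuron's bit flipped independently with probability ``flip_noise``
    (default: ``edge_noise``).
    """
    if np.isscalar(pool_sizes):
        pool_sizes = [int(pool_sizes)] * n_pools
    if len(pool_sizes) != n_pools or any(s <= 0 for s in pool_sizes):
        raise ValueError("need one positive size per pool")
    if not 0 <= edge_noise < 0.5:
        raise ValueError("edge_noise must lie in [0, 0.5)")
    if flip_noise is None:
        flip_noise = edge_noise

    n = int(sum(pool_sizes))
    bounds = np.cumsum([0] + list(pool_sizes))
    pool_of = np.repeat(np.arange(n_pools), pool_sizes)

    # on-route mask: source pool k -> target pool k+1
    on_route = np.zeros((n, n), dtype=bool)   # [target, source]
    for k in range(n_pools - (0 if cycle else 1)):
        nxt = (k + 1) % n_pools
        on_route[bounds[nxt]:bounds[nxt + 1], bounds[k]:bounds[k + 1]] = True

    u = rng.random((n, n))
    present = np.where(on_route, u >= edge_noise, u < edge_noise)
    np.fill_diagonal(present, False)
    w = np.where(present, 0.5 + rng.random((n, n)), 0.0)
    sums = w.sum(axis=1, keepdims=True)
    np.divide(w, sums, out=w, where=sums > 0)

    schedule = np.arange(raster_steps) % n_pools
    x = (pool_of[:, None] == schedule[None, :])
    flips = rng.random((n, raster_steps)) < flip_noise
    x = np.where(flips, ~x, x).astype(np.uint8)
    raster = SpikeRaster(activity=x, start_step=0,
                         neuron_ids=np.arange(n))
    return w, raster
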