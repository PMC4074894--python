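"""Long-horizon simulation driver: snapshots, rasters, metrics, stability.

A run produces a :class:`RunRecord` holding state snapshots at configured
steps, short spike rasters recorded at each snapshot (and at the end of the
run), and per-step time series of the excitatory-to-excitatory connection
count and the population firing rate, plus a subsampled series of the
reciprocal-connection fraction.  Everything is deterministic given the
seed: one `numpy.random.Generator` is threaded through initialization and
every step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import maximum_filter1d, minimum_filter1d

from .core import full_step, initialize_network
from .params import SornParams
from .state import NetworkState

__all__ = ["SimulationConfig", "SpikeRaster", "RunRecord", "run",
           "detect_stable_phase"]

logger = logging.getLogger(__name__)

#: Development-phase snapshot steps: initial, early, intermediate, late and
#: final phase of a long run.
DEFAULT_SNAPSHOT_STEPS = (1, 20_000, 500_000, 1_000_000, 4_000_000)


@dataclass
class SimulationConfig:
    """Run-length and recording schedule for :func:`run`."""

    total_steps: int = 1_000_000
    snapshot_steps: tuple[int, ...] = DEFAULT_SNAPSHOT_STEPS
    raster_window: int = 500        # steps of activity recorded per snapshot
    corr_window: int = 5_000        # length of the final (correlation) raster
    stability_window: int = 50_000  # trailing window for plateau detection
    stability_tol: float = 0.01     # relative (max-min)/mean threshold
    bidir_every: int = 1_000        # stride of the reciprocal-fraction series

    def __post_init__(self) -> None:
        if self.total_steps < 0:
            raise ValueError("total_steps must be >= 0")
        self.snapshot_steps = tuple(
            s for s in sorted(self.snapshot_steps) if s <= self.total_steps)


@dataclass
class SpikeRaster:
    """Binary activity block: ``activity[n, k]`` is neuron ``n`` at step
    ``start_step + k``."""

    activity: np.ndarray        # uint8, neurons x steps
    start_step: int
    neuron_ids: np.ndarray

    @property
    def n_steps(self) -> int:
        return self.activity.shape[1]


@dataclass
class RunRecord:
    """Everything produced by one simulation run."""

    params: SornParams
    config: SimulationConfig
    seed: int
    initial_state: NetworkState
    final_state: NetworkState
    snapshots: dict[int, NetworkState] = field(default_factory=dict)
    rasters: dict[int, SpikeRaster] = field(default_factory=dict)
    ee_count: np.ndarray = None       # int32, per step (len total_steps + 1)
    mean_rate: np.ndarray = None      # float32, per step (len total_steps)
    bidir: pd.DataFrame = None        # columns: step, fraction
    stable_step: int | None = None

    @property
    def final_raster(self) -> SpikeRaster:
        """Raster covering the last ``raster_window`` steps of the run."""
        key = max(self.rasters)
        return self.rasters[key]

    @property
    def metrics(self) -> pd.DataFrame:
        """Per-step metrics table (step, ee_count, mean_rate)."""
        n = len(self.mean_rate)
        return pd.DataFrame({
            "step": np.arange(1, n + 1),
            "ee_count": self.ee_count[1:],
            "mean_rate": self.mean_rate,
        })


def _bidir_fraction(state: NetworkState) -> float:
    a = state.w > 0
    n = state.n_excitatory
    return float(np.count_nonzero(a & a.T) / 2 / n ** 2)


def run(params: SornParams, config: SimulationConfig | None = None,
        disabled: frozenset[str] = frozenset(),
        rng: np.random.Generator | None = None,
        log_every: int | None = None) -> RunRecord:
    """Simulate a SORN for ``config.total_steps`` steps.

    ``disabled`` is forwarded to :func:`sorn.core.full_step` (mechanism
    ablations).  Raises ``FloatingPointError`` if the state becomes
    non-finite, which signals a numerically broken configuration.
    """
    if config is None:
        config = SimulationConfig()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    state = initialize_network(params, rng)
    record = RunRecord(params=params, config=config, seed=params.seed,
                       initial_state=state.copy(), final_state=state)

    total = config.total_steps
    n_e = state.n_excitatory
    ee_count = np.empty(total + 1, dtype=np.int32)
    ee_count[0] = state.ee_count
    mean_rate = np.empty(total, dtype=np.float32)
    bidir_steps, bidir_vals = [0], [_bidir_fraction(state)]

    # raster recording windows: [s, s + raster_window) for each snapshot
    # step s, plus a longer tail window used for activity correlations
    windows = {s: config.raster_window for s in config.snapshot_steps}
    tail_start = max(total - config.corr_window, 0)
    windows[tail_start] = max(windows.get(tail_start, 0),
                              min(config.corr_window, total - tail_start)
                              or 1)
    raster_buf: dict[int, list] = {}

    if 0 in windows:
        record.snapshots[0] = state.copy()

    count = ee_count[0]
    for step in range(1, total + 1):
        info = full_step(state, params, rng, disabled=disabled)
        count += (1 if info.added is not None else 0) - info.n_removed
        ee_count[step] = count
        mean_rate[step - 1] = info.n_active / n_e

        for start, length in windows.items():
            if start <= step - 1 < start + length:
                raster_buf.setdefault(start, []).append(state.x_curr.copy())
        if step in windows and step in config.snapshot_steps:
            record.snapshots[step] = state.copy()
        if step % config.bidir_every == 0 or step == total:
            bidir_steps.append(step)
            bidir_vals.append(_bidir_fraction(state))
        if log_every and step % log_every == 0:
            logger.info("step %d: ee_count=%d rate=%.4f",
                        step, count, mean_rate[step - 1])
            if not np.isfinite(state.t_e).all():
                raise FloatingPointError("non-finite thresholds encountered")

    if not (np.isfinite(state.w).all() and np.isfinite(state.t_e).all()):
        raise FloatingPointError("non-finite state after run")

    for start, rows in raster_buf.items():
        record.rasters[start] = SpikeRaster(
            activity=np.array(rows, dtype=np.uint8).T,
            start_step=start + 1,
            neuron_ids=np.arange(n_e))
    record.ee_count = ee_count
    record.mean_rate = mean_rate
    record.bidir = pd.DataFrame({"step": bidir_steps, "fraction": bidir_vals})
    record.final_state = state

    stride = max(1, config.stability_window // 500)
    sub = ee_count[::stride].astype(np.float64)
    win = max(2, config.stability_window // stride)
    idx = detect_stable_phase(sub, win, config.stability_tol)
    record.stable_step = None if idx is None else int(idx * stride)
    return record


def detect_stable_phase(ee_count_series: np.ndarray, window: int,
                        tol: float) -> int | None:
    """Earliest index whose trailing ``window`` samples form a plateau.

    A plateau means ``(max - min) / mean < tol`` over the window.  Returns
    ``None`` if the series never stabilizes or is shorter than the window.
    """
    s = np.asarray(ee_count_series, dtype=np.float64)
    n = s.size
    if n < window or window < 1:
        return None
    # trailing-window running extrema (window ending at each index)
    origin = (window - 1) // 2
    hi = maximum_filter1d(s, size=window, origin=origin, mode="nearest")
    lo = minimum_filter1d(s, size=window, origin=origin, mode="nearest")
    csum = np.concatenate([[0.0], np.cumsum(s)])
    means = (csum[window:] - csum[:-window]) / window
    spread = hi[window - 1:] - lo[window - 1:]
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(means > 0, spread / means,
                       np.where(spread == 0, 0.0, np.inf))
    hits = np.flatnonzero(rel < tol)
    if hits.size == 0:
        return None
    return int(hits[0] + window - 1)
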