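"""Network state: weight matrices, thresholds, activity history.

The excitatory-to-excitatory matrix ``W^EE`` follows the convention that
entry ``(i, j)`` is the strength of the synapse from presynaptic neuron
``j`` onto postsynaptic neuron ``i``.  It is stored as a dense array in
which 0 encodes "no synapse" (existing synapses always carry strictly
positive weights), mirrored by explicit row/column adjacency lists that the
simulation kernels iterate over (see :mod:`sorn._kernels`).

Inhibitory-to-excitatory weights ``W^EI`` live on a fixed topology recorded
in ``ei_mask``; their values may be driven to 0 by inhibitory STDP but the
synapses themselves are never removed.  ``W^IE`` (excitatory onto
inhibitory) is dense, row-normalized, and immutable.  There are no
inhibitory-to-inhibitory connections.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

__all__ = ["NetworkState", "save_snapshot", "load_snapshot"]

_GROW = 32  # adjacency-list capacity growth increment


@dataclass
class NetworkState:
    """Complete mutable state of a SORN at one time step."""

    w: np.ndarray            # dense N^E x N^E, 0 = absent
    row_cols: np.ndarray     # int64 (N^E, cap), sorted support of each row
    row_len: np.ndarray      # int64 (N^E,)
    col_rows: np.ndarray     # int64 (N^E, cap), support of each column
    col_len: np.ndarray      # int64 (N^E,)
    w_ei: np.ndarray         # dense N^E x N^I
    ei_mask: np.ndarray      # bool N^E x N^I, fixed topology
    w_ie: np.ndarray         # dense N^I x N^E, fixed
    t_e: np.ndarray          # float N^E
    t_i: np.ndarray          # float N^I
    h_ip: np.ndarray         # float N^E, per-neuron target rates
    x_curr: np.ndarray       # uint8 N^E
    x_prev: np.ndarray       # uint8 N^E
    y_curr: np.ndarray       # uint8 N^I
    y_prev: np.ndarray       # uint8 N^I
    t: int = 0
    seed: int | None = None

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_matrices(cls, w_ee, w_ei, w_ie, t_e, t_i, h_ip,
                      ei_mask=None, t=0, seed=None) -> "NetworkState":
        """Build a state from explicit matrices (dense or scipy sparse).

        The support of ``w_ee`` is taken to be its strictly positive
        entries; the diagonal must be empty.  ``ei_mask`` defaults to the
        nonzero pattern of ``w_ei``.
        """
        w = np.asarray(sp.csr_matrix(w_ee).todense(), dtype=np.float64) \
            if sp.issparse(w_ee) else np.array(w_ee, dtype=np.float64)
        if np.any(np.diag(w) != 0):
            raise ValueError("W^EE must have an empty diagonal")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        n_e = w.shape[0]
        w_ei = np.array(w_ei, dtype=np.float64)
        n_i = w_ei.shape[1]
        if ei_mask is None:
            ei_mask = w_ei > 0
        state = cls(
            w=w,
            row_cols=np.zeros((n_e, 0), dtype=np.int64),
            row_len=np.zeros(n_e, dtype=np.int64),
            col_rows=np.zeros((n_e, 0), dtype=np.int64),
            col_len=np.zeros(n_e, dtype=np.int64),
            w_ei=w_ei,
            ei_mask=np.array(ei_mask, dtype=bool),
            w_ie=np.array(w_ie, dtype=np.float64),
            t_e=np.array(t_e, dtype=np.float64),
            t_i=np.array(t_i, dtype=np.float64),
            h_ip=np.array(h_ip, dtype=np.float64),
            x_curr=np.zeros(n_e, dtype=np.uint8),
            x_prev=np.zeros(n_e, dtype=np.uint8),
            y_curr=np.zeros(n_i, dtype=np.uint8),
            y_prev=np.zeros(n_i, dtype=np.uint8),
            t=t,
            seed=seed,
        )
        state._rebuild_adjacency()
        return state

    def _rebuild_adjacency(self) -> None:
        """Recompute the adjacency lists from the dense matrix."""
        n_e = self.n_excitatory
        fan_in = np.count_nonzero(self.w > 0, axis=1)
        fan_out = np.count_nonzero(self.w > 0, axis=0)
        cap_r = int(fan_in.max(initial=0)) + _GROW
        cap_c = int(fan_out.max(initial=0)) + _GROW
        self.row_cols = np.zeros((n_e, cap_r), dtype=np.int64)
        self.row_len = np.zeros(n_e, dtype=np.int64)
        self.col_rows = np.zeros((n_e, cap_c), dtype=np.int64)
        self.col_len = np.zeros(n_e, dtype=np.int64)
        for i in range(n_e):
            cols = np.flatnonzero(self.w[i] > 0)
            self.row_len[i] = cols.size
            self.row_cols[i, :cols.size] = cols
        for j in range(n_e):
            rows = np.flatnonzero(self.w[:, j] > 0)
            self.col_len[j] = rows.size
            self.col_rows[j, :rows.size] = rows

    # -- basic properties -------------------------------------------------

    @property
    def n_excitatory(self) -> int:
        return self.w.shape[0]

    @property
    def n_inhibitory(self) -> int:
        return self.w_ei.shape[1]

    @property
    def ee_count(self) -> int:
        """Number of existing excitatory-to-excitatory synapses."""
        return int(self.row_len.sum())

    @property
    def w_ee(self) -> sp.csr_matrix:
        """The W^EE matrix as a scipy CSR sparse matrix (a copy)."""
        return sp.csr_matrix(self.w)

    def ee_weight(self, i: int, j: int) -> float:
        """Weight of the synapse j -> i, or 0.0 if absent."""
        return float(self.w[i, j])

    def has_ee_synapse(self, i: int, j: int) -> bool:
        return self.w[i, j] > 0

    # -- mutation helpers -------------------------------------------------

    def ensure_capacity(self, i: int, j: int) -> None:
        """Grow the adjacency lists so a synapse (i, j) can be inserted."""
        if self.row_len[i] >= self.row_cols.shape[1]:
            self.row_cols = np.hstack([
                self.row_cols,
                np.zeros((self.n_excitatory, _GROW), dtype=np.int64)])
        if self.col_len[j] >= self.col_rows.shape[1]:
            self.col_rows = np.hstack([
                self.col_rows,
                np.zeros((self.n_excitatory, _GROW), dtype=np.int64)])

    def add_ee_synapse(self, i: int, j: int, weight: float) -> None:
        """Create the synapse j -> i with the given strength."""
        if i == j:
            raise ValueError("self-connections are not allowed")
        if weight <= 0:
            raise ValueError("synaptic weights must be positive")
        if self.w[i, j] > 0:
            raise ValueError(f"synapse ({i}, {j}) already exists")
        self.ensure_capacity(i, j)
        ln = self.row_len[i]
        pos = np.searchsorted(self.row_cols[i, :ln], j)
        self.row_cols[i, pos + 1:ln + 1] = self.row_cols[i, pos:ln]
        self.row_cols[i, pos] = j
        self.row_len[i] += 1
        self.col_rows[j, self.col_len[j]] = i
        self.col_len[j] += 1
        self.w[i, j] = weight

    def remove_ee_synapse(self, i: int, j: int) -> None:
        if self.w[i, j] <= 0:
            raise ValueError(f"synapse ({i}, {j}) does not exist")
        self.w[i, j] = 0.0
        ln = self.row_len[i]
        pos = np.searchsorted(self.row_cols[i, :ln], j)
        self.row_cols[i, pos:ln - 1] = self.row_cols[i, pos + 1:ln]
        self.row_len[i] -= 1
        ln = self.col_len[j]
        rows = self.col_rows[j, :ln]
        pos = int(np.flatnonzero(rows == i)[0])
        self.col_rows[j, pos] = self.col_rows[j, ln - 1]
        self.col_len[j] -= 1

    def copy(self) -> "NetworkState":
        return NetworkState(
            w=self.w.copy(), row_cols=self.row_cols.copy(),
            row_len=self.row_len.copy(), col_rows=self.col_rows.copy(),
            col_len=self.col_len.copy(), w_ei=self.w_ei.copy(),
            ei_mask=self.ei_mask.copy(), w_ie=self.w_ie.copy(),
            t_e=self.t_e.copy(), t_i=self.t_i.copy(), h_ip=self.h_ip.copy(),
            x_curr=self.x_curr.copy(), x_prev=self.x_prev.copy(),
            y_curr=self.y_curr.copy(), y_prev=self.y_prev.copy(),
            t=self.t, seed=self.seed)

    def equals(self, other: "NetworkState") -> bool:
        """Exact (bitwise) equality of all dynamical quantities."""
        if self.t != other.t:
            return False
        if not (np.array_equal(self.w, other.w)
                and np.array_equal(self.w_ei, other.w_ei)
                and np.array_equal(self.w_ie, other.w_ie)):
            return False
        return (np.array_equal(self.t_e, other.t_e)
                and np.array_equal(self.t_i, other.t_i)
                and np.array_equal(self.h_ip, other.h_ip)
                and np.array_equal(self.x_curr, other.x_curr)
                and np.array_equal(self.x_prev, other.x_prev)
                and np.array_equal(self.y_curr, other.y_curr)
                and np.array_equal(self.y_prev, other.y_prev))

    def check_invariants(self, scaling_active: bool = True,
                         tol: float = 1e-9) -> None:
        """Assert the structural invariants; raises AssertionError."""
        assert np.all(np.diag(self.w) == 0), "self-connection present"
        assert np.all(self.w >= 0) and np.all(self.w_ei >= 0), \
            "negative weight"
        if scaling_active:
            sums = self.w.sum(axis=1)
            nonempty = self.row_len > 0
            assert np.all(np.abs(sums[nonempty] - 1.0) < tol), \
                "EE row sums deviate from 1"


# -- snapshot persistence -------------------------------------------------
#
# A snapshot directory holds one MatrixMarket file per weight matrix plus a
# JSON sidecar with the vectors, counters and seed.

def save_snapshot(state: NetworkState, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mmwrite(out / "w_ee.mtx", sp.coo_matrix(state.w), precision=17)
    # record the EI topology explicitly so clamped-to-zero synapses survive
    # the round trip
    ii, kk = np.nonzero(state.ei_mask)
    mmwrite(out / "w_ei.mtx",
            sp.coo_matrix((state.w_ei[ii, kk], (ii, kk)),
                          shape=state.w_ei.shape), precision=17)
    mmwrite(out / "ei_mask.mtx", sp.coo_matrix(state.ei_mask.astype(np.int8)))
    mmwrite(out / "w_ie.mtx", np.asarray(state.w_ie), precision=17)
    sidecar = {
        "t": state.t,
        "seed": state.seed,
        "t_e": state.t_e.tolist(),
        "t_i": state.t_i.tolist(),
        "h_ip": state.h_ip.tolist(),
        "x_curr": state.x_curr.tolist(),
        "x_prev": state.x_prev.tolist(),
        "y_curr": state.y_curr.tolist(),
        "y_prev": state.y_prev.tolist(),
    }
    (out / "state.json").write_text(json.dumps(sidecar) + "\n")


def load_snapshot(in_dir: str | Path) -> NetworkState:
    src = Path(in_dir)
    side = json.loads((src / "state.json").read_text())
    w_ee = sp.csr_matrix(mmread(src / "w_ee.mtx"))
    w_ei = np.asarray(mmread(src / "w_ei.mtx").todense(), dtype=np.float64)
    ei_mask = np.asarray(mmread(src / "ei_mask.mtx").todense()) > 0
    w_ie = np.asarray(mmread(src / "w_ie.mtx"), dtype=np.float64)
    state = NetworkState.from_matrices(
        w_ee, w_ei, w_ie,
        t_e=side["t_e"], t_i=side["t_i"], h_ip=side["h_ip"],
        ei_mask=ei_mask, t=side["t"], seed=side["seed"])
    state.x_curr = np.array(side["x_curr"], dtype=np.uint8)
    state.x_prev = np.array(side["x_prev"], dtype=np.uint8)
    state.y_curr = np.array(side["y_curr"], dtype=np.uint8)
    state.y_prev = np.array(side["y_prev"], dtype=np.uint8)
    return state
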