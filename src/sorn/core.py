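"""Single-step dynamics and the five plasticity mechanisms of the SORN.

Update equations (per time step, all neurons binary)::

    x_i(t+1) = Theta( sum_j W^EE_ij x_j(t) - sum_k W^EI_ik y_k(t)
                      - T^E_i + xi^E_i(t) )
    y_i(t+1) = Theta( sum_j W^IE_ij x_j(t) - T^I_i + xi^I_i(t) )

with ``Theta`` the Heaviside step function using the convention
``Theta(0) = 0`` (strictly positive total drive is required to fire; with
continuous Gaussian noise the boundary case has probability zero, and a
fixed convention keeps reference implementations exact).

Plasticity rules applied once per step:

* STDP (excitatory): ``dW^EE_ij = eta_stdp * (x_i(t) x_j(t-1)
  - x_i(t-1) x_j(t))``; a synapse whose weight would become <= 0 is
  removed from the topology.
* Inhibitory STDP: ``dW^EI_ij = -eta_inhib * y_j(t-1) *
  (1 - x_i(t) * (1 + 1/mu_istdp))``; weights clamp at 0, topology fixed.
* Structural plasticity: with probability ``p_struct`` one new synapse of
  strength ``w_struct_init`` appears between a uniformly chosen unconnected
  ordered excitatory pair.
* Synaptic scaling: every nonempty row of ``W^EE`` is divided by its sum.
* Intrinsic plasticity: ``T^E_i += eta_ip * (x_i(t) - H^IP_i)``;
  thresholds are unbounded after initialization.

:func:`full_step` composes them in the order: draw noise -> activity
update -> history shift -> STDP -> inhibitory STDP -> structural
plasticity -> synaptic scaling -> intrinsic plasticity.  Scaling running
after all weight changes makes the row-sum invariant exact at the end of
every step; intrinsic plasticity runs last so it sees the just-computed
activity.

Randomness protocol
-------------------
All stochastic operations consume a single ``numpy.random.Generator``.
:func:`full_step` draws, in this exact order:

1. ``rng.normal(0, sqrt(noise_var), n_excitatory)`` — excitatory noise,
2. ``rng.normal(0, sqrt(noise_var), n_inhibitory)`` — inhibitory noise,
3. if structural plasticity is enabled and the graph is not complete:
   ``rng.random()`` compared against ``p_struct``; on success, repeated
   ``rng.integers(0, n_excitatory, size=2)`` draws (at most 64) until they
   name an unconnected off-diagonal pair, falling back to
   ``rng.integers(n_candidates)`` over the row-major list of unconnected
   pairs.  Rejection sampling is exactly uniform over the candidate pairs.

Reference implementations reproduce the simulator bit for bit by following
this protocol together with the ascending-index sequential summation order
described in :mod:`sorn._kernels`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._kernels import step_phase_a, step_phase_b
from .params import SornParams
from .state import NetworkState

__all__ = [
    "MECHANISMS", "StepInfo", "initialize_network", "update_activity",
    "apply_stdp", "apply_istdp", "synaptic_scaling", "intrinsic_plasticity",
    "structural_plasticity", "full_step",
]

#: Names accepted by the ``disabled`` argument of :func:`full_step`.
MECHANISMS = frozenset({"stdp", "istdp", "scaling", "structural", "intrinsic"})

_MAX_REJECTION_TRIES = 64


@dataclass(frozen=True)
class StepInfo:
    """What happened during one :func:`full_step`."""
    n_active: int                    # excitatory spikes at the new step
    n_removed: int                   # synapses eliminated by STDP
    added: tuple[int, int] | None    # structurally created synapse (i, j)


# -- initialization -------------------------------------------------------

def initialize_network(params: SornParams,
                       rng: np.random.Generator | None = None
                       ) -> NetworkState:
    """Draw a random initial network state.

    ``W^EE`` gets each off-diagonal entry independently with probability
    ``p_ee_init``; values follow ``init_distribution`` and each nonempty
    row is then rescaled to sum to one, so the synaptic-scaling invariant
    holds from step 0.  ``W^EI`` entries exist with probability
    ``p_ei_init`` and keep their raw uniform values (no row normalization).
    ``W^IE`` is all-to-all with uniform values normalized to row sums of
    one, and never changes afterwards.

    Raises ``ValueError`` if the realized excitatory graph has no synapse.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n_e, n_i = params.n_excitatory, params.n_inhibitory

    mask = rng.random((n_e, n_e)) < params.p_ee_init
    np.fill_diagonal(mask, False)
    dist = params.init_distribution
    if dist == "uniform":
        vals = rng.random((n_e, n_e))
    elif dist == "gaussian":
        vals = np.abs(rng.normal(0.0, 1.0, (n_e, n_e)))
    elif dist == "delta":
        vals = np.ones((n_e, n_e))
    else:  # exponential
        vals = rng.exponential(1.0, (n_e, n_e))
    w_ee = np.where(mask, vals, 0.0)
    if not np.any(w_ee > 0):
        raise ValueError("realized excitatory graph is empty; "
                         "increase p_ee_init or n_excitatory")
    sums = w_ee.sum(axis=1, keepdims=True)
    np.divide(w_ee, sums, out=w_ee, where=sums > 0)

    ei_mask = rng.random((n_e, n_i)) < params.p_ei_init
    w_ei = np.where(ei_mask, rng.random((n_e, n_i)), 0.0)

    w_ie = rng.random((n_i, n_e))
    w_ie /= w_ie.sum(axis=1, keepdims=True)

    t_e = rng.uniform(0.0, params.t_e_max, n_e)
    t_i = rng.uniform(0.0, params.t_i_max, n_i)
    h_ip = rng.uniform(params.mu_ip - params.sigma_hip,
                       params.mu_ip + params.sigma_hip, n_e)

    return NetworkState.from_matrices(
        w_ee, w_ei, w_ie, t_e, t_i, h_ip, ei_mask=ei_mask,
        t=0, seed=params.seed)


# -- individual operations ------------------------------------------------
#
# Each operation is a thin wrapper around the same compiled kernels that
# full_step uses, so composing them by hand is bitwise identical to the
# fused step.  Operations mutate the state in place and return it.

def update_activity(state: NetworkState, params: SornParams,
                    noise_e: np.ndarray, noise_i: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Compute the next activity vectors without touching the state."""
    x_new, y_new, _, _ = step_phase_a(
        state.w, state.row_cols, state.row_len, state.col_rows,
        state.col_len, state.w_ei, state.ei_mask, state.w_ie,
        state.t_e, state.t_i,
        state.x_curr, state.x_prev, state.y_curr, state.y_prev,
        np.asarray(noise_e, dtype=np.float64),
        np.asarray(noise_i, dtype=np.float64),
        params.eta_stdp, params.eta_inhib, 1.0 + 1.0 / params.mu_istdp,
        True, False, False, False)
    return x_new, y_new


def apply_stdp(state: NetworkState, params: SornParams) -> NetworkState:
    """Causal STDP on existing EE synapses, with elimination."""
    _dummy = np.zeros(0)
    step_phase_a(
        state.w, state.row_cols, state.row_len, state.col_rows,
        state.col_len, state.w_ei, state.ei_mask, state.w_ie,
        state.t_e, state.t_i,
        state.x_curr, state.x_prev, state.y_curr, state.y_prev,
        _dummy, _dummy,
        params.eta_stdp, params.eta_inhib, 1.0 + 1.0 / params.mu_istdp,
        False, False, True, False)
    return state


def apply_istdp(state: NetworkState, params: SornParams) -> NetworkState:
    """Inhibitory STDP on the fixed EI topology (weights clamp at 0)."""
    _dummy = np.zeros(0)
    step_phase_a(
        state.w, state.row_cols, state.row_len, state.col_rows,
        state.col_len, state.w_ei, state.ei_mask, state.w_ie,
        state.t_e, state.t_i,
        state.x_curr, state.x_prev, state.y_curr, state.y_prev,
        _dummy, _dummy,
        params.eta_stdp, params.eta_inhib, 1.0 + 1.0 / params.mu_istdp,
        False, False, False, True)
    return state


def synaptic_scaling(state: NetworkState) -> NetworkState:
    """Divide every nonempty EE row by its sum (multiplicative scaling)."""
    step_phase_b(
        state.w, state.row_cols, state.row_len, state.col_rows,
        state.col_len, state.t_e, state.h_ip, state.x_curr,
        -1, -1, 0.0, 0.0, True, False)
    return state


def intrinsic_plasticity(state: NetworkState,
                         params: SornParams) -> NetworkState:
    """Move each excitatory threshold toward its target firing rate."""
    step_phase_b(
        state.w, state.row_cols, state.row_len, state.col_rows,
        state.col_len, state.t_e, state.h_ip, state.x_curr,
        -1, -1, 0.0, params.eta_ip, False, True)
    return state


def _choose_structural_pair(state: NetworkState, params: SornParams,
                            rng: np.random.Generator
                            ) -> tuple[int, int] | None:
    """Uniformly choose an unconnected ordered pair, or None to skip.

    Follows the randomness protocol in the module docstring.  Returns None
    either when the per-step coin comes up tails or when the graph is
    complete.
    """
    n_e = state.n_excitatory
    if state.ee_count >= n_e * (n_e - 1):
        return None
    if rng.random() >= params.p_struct:
        return None
    for _ in range(_MAX_REJECTION_TRIES):
        i, j = rng.integers(0, n_e, size=2)
        if i != j and state.w[i, j] == 0.0:
            return int(i), int(j)
    # dense graph: enumerate candidates (row-major) and pick one uniformly
    free = (state.w == 0.0)
    np.fill_diagonal(free, False)
    cand = np.argwhere(free)
    i, j = cand[rng.integers(len(cand))]
    return int(i), int(j)


def structural_plasticity(state: NetworkState, params: SornParams,
                          rng: np.random.Generator) -> NetworkState:
    """With probability ``p_struct`` add one new weak EE synapse."""
    pair = _choose_structural_pair(state, params, rng)
    if pair is not None:
        state.add_ee_synapse(pair[0], pair[1], params.w_struct_init)
    return state


# -- the canonical composed step ------------------------------------------

def full_step(state: NetworkState, params: SornParams,
              rng: np.random.Generator,
              disabled: frozenset[str] = frozenset(),
              debug: bool = False) -> StepInfo:
    """Advance the network by one time step (in place).

    ``disabled`` names plasticity mechanisms (subset of
    :data:`MECHANISMS`) whose updates are skipped — used by the ablation
    experiments.  ``debug=True`` asserts the state invariants afterwards
    (row-sum check only while scaling is active).
    """
    unknown = disabled - MECHANISMS
    if unknown:
        raise ValueError(f"unknown mechanisms: {sorted(unknown)}")
    sigma = math.sqrt(params.noise_var)
    noise_e = rng.normal(0.0, sigma, state.n_excitatory)
    noise_i = rng.normal(0.0, sigma, state.n_inhibitory)

    _, _, n_active, n_removed = step_phase_a(
        state.w, state.row_cols, state.row_len, state.col_rows,
        state.col_len, state.w_ei, state.ei_mask, state.w_ie,
        state.t_e, state.t_i,
        state.x_curr, state.x_prev, state.y_curr, state.y_prev,
        noise_e, noise_i,
        params.eta_stdp, params.eta_inhib, 1.0 + 1.0 / params.mu_istdp,
        True, True, "stdp" not in disabled, "istdp" not in disabled)

    added = None
    if "structural" not in disabled:
        added = _choose_structural_pair(state, params, rng)
    add_i, add_j = added if added is not None else (-1, -1)
    if added is not None:
        state.ensure_capacity(add_i, add_j)

    step_phase_b(
        state.w, state.row_cols, state.row_len, state.col_rows,
        state.col_len, state.t_e, state.h_ip, state.x_curr,
        add_i, add_j, params.w_struct_init, params.eta_ip,
        "scaling" not in disabled, "intrinsic" not in disabled)

    state.t += 1
    if debug:
        state.check_invariants(scaling_active="scaling" not in disabled)
    return StepInfo(n_active=n_active, n_removed=n_removed, added=added)
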