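"""Unit tests of initialization, single-step dynamics and plasticity rules."""

import numpy as np
import pytest
from scipy import stats

from sorn import (SornParams, apply_istdp, apply_stdp, full_step,
                  initialize_network, intrinsic_plasticity, NetworkState,
                  structural_plasticity, synaptic_scaling, update_activity)


def _two_neuron_state(w=None, w_12=0.0, t_e=(0.5, 0.5)):
    """Minimal 2E+1I network with controllable weights."""
    w_ee = np.zeros((2, 2))
    if w is not None:
        w_ee[1, 0] = w
    w_ee[0, 1] = w_12
    return NetworkState.from_matrices(
        w_ee, w_ei=np.zeros((2, 1)), w_ie=np.ones((1, 2)) / 2,
        t_e=np.array(t_e), t_i=np.array([0.25]), h_ip=np.array([0.1, 0.1]))


# -- initialization -------------------------------------------------------

def test_initializer_shapes_and_normalization():
    p = SornParams(n_excitatory=200, seed=3)
    st = initialize_network(p)
    assert st.w.shape == (200, 200) and st.w_ie.shape == (40, 200)
    assert np.all(np.diag(st.w) == 0)
    # every W^IE row normalized to 1; every nonempty W^EE row too
    assert np.allclose(st.w_ie.sum(axis=1), 1.0, atol=1e-12)
    sums = st.w.sum(axis=1)
    assert np.allclose(sums[st.row_len > 0], 1.0, atol=1e-12)
    # thresholds within their initial intervals, target rates at mu_ip
    assert st.t_e.min() >= 0 and st.t_e.max() <= p.t_e_max
    assert st.t_i.min() >= 0 and st.t_i.max() <= p.t_i_max
    assert np.all(st.h_ip == p.mu_ip)
    assert not st.x_curr.any() and not st.y_curr.any()


def test_initializer_density_within_binomial_ci():
    p = SornParams(n_excitatory=200, seed=11)
    st = initialize_network(p)
    n_pairs = 200 * 199
    lo, hi = stats.binom.interval(0.999, n_pairs, p.p_ee_init)
    assert lo <= st.ee_count <= hi


def test_delta_initial_weights_uniform_within_rows():
    p = SornParams(n_excitatory=50, init_distribution="delta", seed=5)
    st = initialize_network(p)
    for i in range(50):
        ln = st.row_len[i]
        if ln:
            vals = st.w[i][st.w[i] > 0]
            assert np.allclose(vals, 1.0 / ln, atol=1e-12)


def test_initializer_deterministic_under_seed():
    p = SornParams(n_excitatory=60, seed=21)
    assert initialize_network(p).equals(initialize_network(p))


def test_empty_realized_graph_rejected():
    p = SornParams(n_excitatory=5, p_ee_init=0.01, seed=0)
    # a 5-neuron graph at p=0.01 is almost surely empty for some seed
    with pytest.raises(ValueError):
        for seed in range(50):
            initialize_network(p.replace(seed=seed))


@pytest.mark.parametrize("dist", ["uniform", "gaussian", "delta",
                                  "exponential"])
def test_all_initial_distributions_give_valid_states(dist):
    st = initialize_network(
        SornParams(n_excitatory=40, init_distribution=dist, seed=2))
    st.check_invariants()


# -- activity update ------------------------------------------------------

def test_no_drive_no_spikes():
    st = _two_neuron_state()
    p = SornParams(n_excitatory=2, n_inhibitory=1)
    x, y = update_activity(st, p, np.zeros(2), np.zeros(1))
    assert not x.any() and not y.any()


def test_suprathreshold_drive_fires():
    st = _two_neuron_state(w=1.0)
    st.x_curr[0] = 1  # presynaptic neuron active, weight 1.0 onto neuron 1
    p = SornParams(n_excitatory=2, n_inhibitory=1)
    x, _ = update_activity(st, p, np.zeros(2), np.zeros(1))
    assert x[1] == 1 and x[0] == 0  # Theta(1 - 0.5) = 1


def test_threshold_equality_does_not_fire():
    # total drive exactly 0 must not produce a spike: Theta(0) = 0
    st = _two_neuron_state(w=0.5, t_e=(0.5, 0.5))
    st.x_curr[0] = 1
    p = SornParams(n_excitatory=2, n_inhibitory=1)
    x, _ = update_activity(st, p, np.zeros(2), np.zeros(1))
    assert x[1] == 0


# -- STDP -----------------------------------------------------------------

def test_stdp_causal_potentiation_and_antisymmetry():
    st = _two_neuron_state(w=0.5, w_12=0.5)
    p = SornParams(n_excitatory=2, n_inhibitory=1)
    # causal event: 0 fired at t-1, 1 fires at t
    st.x_prev[:] = (1, 0)
    st.x_curr[:] = (0, 1)
    apply_stdp(st, p)
    assert st.w[1, 0] == 0.5 + p.eta_stdp   # pre-before-post potentiated
    assert st.w[0, 1] == 0.5 - p.eta_stdp   # post-before-pre depressed


def test_stdp_simultaneous_firing_is_neutral():
    st = _two_neuron_state(w=0.5, w_12=0.5)
    p = SornParams(n_excitatory=2, n_inhibitory=1)
    st.x_prev[:] = (1, 1)
    st.x_curr[:] = (1, 1)
    apply_stdp(st, p)
    assert st.w[1, 0] == 0.5 and st.w[0, 1] == 0.5


def test_stdp_eliminates_weak_acausal_synapse():
    st = _two_neuron_state(w=0.001)   # synapse 0 -> 1
    p = SornParams(n_excitatory=2, n_inhibitory=1)
    st.x_prev[:] = (0, 1)   # post fired first ...
    st.x_curr[:] = (1, 0)   # ... pre after: acausal, -eta drives it to <= 0
    apply_stdp(st, p)
    assert st.w[1, 0] == 0.0 and st.ee_count == 0
    assert not st.has_ee_synapse(1, 0)


def test_stdp_never_creates_synapses():
    st = _two_neuron_state(w=0.5)  # only synapse 0 -> 1
    p = SornParams(n_excitatory=2, n_inhibitory=1)
    st.x_prev[:] = (0, 1)
    st.x_curr[:] = (1, 0)   # causal for the absent synapse 1 -> 0
    apply_stdp(st, p)
    assert not st.has_ee_synapse(0, 1)


# -- inhibitory STDP ------------------------------------------------------

def _ei_state(w_ei=0.5):
    st = _two_neuron_state(w=0.5)
    st.w_ei[:] = w_ei
    st.ei_mask[:] = True
    return st


def test_istdp_post_spike_after_inhibition_potentiates():
    st = _ei_state(0.5)
    p = SornParams(n_excitatory=2, n_inhibitory=1)
    st.y_prev[0] = 1
    st.x_curr[:] = (1, 0)
    apply_istdp(st, p)
    # dW = -eta*(1 - 1*(1 + 1/mu)) = -0.001*(1 - 11) = +0.010
    assert np.isclose(st.w_ei[0, 0], 0.5 + 0.010, atol=1e-15)
    # silent postsynaptic neuron is depressed: dW = -eta
    assert np.isclose(st.w_ei[1, 0], 0.5 - 0.001, atol=1e-15)


def test_istdp_requires_presynaptic_inhibitory_spike():
    st = _ei_state(0.5)
    p = SornParams(n_excitatory=2, n_inhibitory=1)
    st.y_prev[0] = 0
    st.x_curr[:] = (1, 1)
    apply_istdp(st, p)
    assert np.all(st.w_ei[st.ei_mask] == 0.5)


def test_istdp_clamps_at_zero_but_keeps_topology():
    st = _ei_state(0.0005)
    p = SornParams(n_excitatory=2, n_inhibitory=1)
    st.y_prev[0] = 1
    st.x_curr[:] = (0, 0)
    apply_istdp(st, p)
    assert np.all(st.w_ei == 0.0)
    assert st.ei_mask.all()  # synapses still exist


def test_istdp_fixed_point_rate():
    """The rule balances at P(post spike | pre inhibitory spike) =
    mu/(1+mu): the Monte-Carlo mean update vanishes there."""
    p = SornParams(n_excitatory=2, n_inhibitory=1)
    rate = p.mu_istdp / (1 + p.mu_istdp)
    rng = np.random.default_rng(0)
    x = rng.random(100_000) < rate
    dw = -p.eta_inhib * (1 - x * (1 + 1 / p.mu_istdp))
    # standard error of the mean at this sample size
    assert abs(dw.mean()) < 3 * dw.std() / np.sqrt(len(dw))


# -- synaptic scaling -----------------------------------------------------

def test_scaling_normalizes_rows_and_preserves_ratios():
    w = np.zeros((3, 3))
    w[0, 1], w[0, 2] = 0.2, 0.6
    w[1, 0] = 2.0
    st = NetworkState.from_matrices(
        w, np.zeros((3, 1)), np.ones((1, 3)) / 3,
        t_e=np.zeros(3), t_i=np.zeros(1), h_ip=np.full(3, 0.1))
    synaptic_scaling(st)
    assert np.allclose([st.w[0, 1], st.w[0, 2]], [0.25, 0.75], atol=1e-15)
    assert st.w[1, 0] == 1.0
    assert np.all(st.w[2] == 0.0)  # empty row untouched
    # idempotence and ratio preservation
    before = st.w.copy()
    synaptic_scaling(st)
    assert np.allclose(st.w, before, atol=1e-15)
    assert np.isclose(st.w[0, 2] / st.w[0, 1], 3.0, atol=1e-12)


# -- intrinsic plasticity -------------------------------------------------

def test_intrinsic_plasticity_arithmetic():
    st = _two_neuron_state()
    p = SornParams(n_excitatory=2, n_inhibitory=1)
    st.x_curr[:] = (1, 0)
    t0 = st.t_e.copy()
    intrinsic_plasticity(st, p)
    assert np.isclose(st.t_e[0] - t0[0], 0.01 * (1 - 0.1), atol=1e-15)
    assert np.isclose(st.t_e[1] - t0[1], 0.01 * (0 - 0.1), atol=1e-15)


def test_intrinsic_plasticity_telescopes_over_windows():
    p = SornParams(n_excitatory=2, n_inhibitory=1)
    st = _two_neuron_state()
    t0 = st.t_e.copy()
    rng = np.random.default_rng(4)
    spikes = np.zeros(2)
    for _ in range(200):
        st.x_curr[:] = rng.integers(0, 2, 2)
        spikes += st.x_curr
        intrinsic_plasticity(st, p)
    expected = p.eta_ip * (spikes - 200 * 0.1)
    assert np.allclose(st.t_e - t0, expected, atol=1e-12)


# -- structural plasticity ------------------------------------------------

def test_structural_is_noop_on_complete_graph(rng):
    n = 5
    w = np.ones((n, n)) / (n - 1)
    np.fill_diagonal(w, 0.0)
    st = NetworkState.from_matrices(
        w, np.zeros((n, 1)), np.ones((1, n)) / n,
        t_e=np.zeros(n), t_i=np.zeros(1), h_ip=np.full(n, 0.1))
    p = SornParams(n_excitatory=n, n_inhibitory=1)
    before = st.w.copy()
    for _ in range(50):
        structural_plasticity(st, p, rng)
    assert np.array_equal(st.w, before)


def test_structural_addition_rate_and_value(small_state, small_params, rng):
    st, p = small_state, small_params
    added = 0
    n_steps = 20_000
    for _ in range(n_steps):
        before = st.ee_count
        structural_plasticity(st, p, rng)
        if st.ee_count != before:
            added += 1
            # undo so the graph stays sparse and every step is comparable
            i, j = np.argwhere((st.w > 0) & (st.w == p.w_struct_init))[-1]
            assert i != j
            st.remove_ee_synapse(i, j)
    lo, hi = stats.binom.interval(0.9999, n_steps, p.p_struct)
    assert lo <= added <= hi


def test_structural_addition_is_uniform_over_free_pairs(rng):
    # 3 neurons, one existing synapse: 5 free ordered pairs
    st = _two_neuron_state(w=0.5)
    w = np.zeros((3, 3))
    w[1, 0] = 1.0
    st = NetworkState.from_matrices(
        w, np.zeros((3, 1)), np.ones((1, 3)) / 3,
        t_e=np.zeros(3), t_i=np.zeros(1), h_ip=np.full(3, 0.1))
    p = SornParams(n_excitatory=3, n_inhibitory=1, p_struct=1.0)
    counts = {}
    for _ in range(5000):
        trial = st.copy()
        structural_plasticity(trial, p, rng)
        new = np.argwhere(trial.w != st.w)
        assert len(new) == 1
        counts[tuple(new[0])] = counts.get(tuple(new[0]), 0) + 1
    assert len(counts) == 5
    _, pval = stats.chisquare(list(counts.values()))
    assert pval > 1e-4


# -- the composed step ----------------------------------------------------

def test_full_step_keeps_invariants(small_state, small_params, rng):
    st = small_state
    for _ in range(500):
        full_step(st, small_params, rng, debug=True)
    assert st.t == 500


def test_full_step_row_sums_exact(small_state, small_params, rng):
    st = small_state
    for _ in range(200):
        full_step(st, small_params, rng)
        sums = st.w.sum(axis=1)
        assert np.all(np.abs(sums[st.row_len > 0] - 1.0) < 1e-9)


def test_full_step_wie_immutable(small_state, small_params, rng):
    st = small_state
    w_ie0 = st.w_ie.copy()
    for _ in range(300):
        full_step(st, small_params, rng)
    assert np.array_equal(st.w_ie, w_ie0)


def test_frozen_plasticity_keeps_weights_constant(small_state, small_params,
                                                  rng):
    st = small_state
    w0, wei0, te0 = st.w.copy(), st.w_ei.copy(), st.t_e.copy()
    disabled = frozenset({"stdp", "istdp", "scaling", "structural",
                          "intrinsic"})
    for _ in range(200):
        full_step(st, small_params, rng, disabled=disabled)
    assert np.array_equal(st.w, w0)
    assert np.array_equal(st.w_ei, wei0)
    assert np.array_equal(st.t_e, te0)


def test_full_step_equals_composed_operations(small_params):
    """The fused step must equal the hand-composed sequence of individual
    operations (same kernels, same order, same RNG protocol)."""
    import math
    from sorn.core import _choose_structural_pair

    p = small_params
    rng_a = np.random.default_rng(99)
    rng_b = np.random.default_rng(99)
    st_a = initialize_network(p, rng_a)
    st_b = initialize_network(p, rng_b)
    for _ in range(100):
        full_step(st_a, p, rng_a)

        sigma = math.sqrt(p.noise_var)
        noise_e = rng_b.normal(0.0, sigma, st_b.n_excitatory)
        noise_i = rng_b.normal(0.0, sigma, st_b.n_inhibitory)
        x_new, y_new = update_activity(st_b, p, noise_e, noise_i)
        st_b.x_prev, st_b.x_curr = st_b.x_curr, x_new
        st_b.y_prev, st_b.y_curr = st_b.y_curr, y_new
        apply_stdp(st_b, p)
        apply_istdp(st_b, p)
        structural_plasticity(st_b, p, rng_b)
        synaptic_scaling(st_b)
        intrinsic_plasticity(st_b, p)
        st_b.t += 1

        assert st_a.equals(st_b)


def test_unknown_mechanism_rejected(small_state, small_params, rng):
    with pytest.raises(ValueError):
        full_step(small_state, small_params, rng,
                  disabled=frozenset({"gravity"}))
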