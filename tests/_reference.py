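"""Straight-line pure-Python SORN reference implementation.

Independent of the package's compiled kernels: dense matrices, explicit
Python loops, sequential ascending-index summation, and the documented
randomness protocol (excitatory noise, inhibitory noise, structural coin,
rejection-sampled pair).  Deliberately slow and simple; used to check the
vectorized engine bit for bit on small networks.
"""

from __future__ import annotations

import math

import numpy as np


class ReferenceSorn:
    """Dense-matrix mirror of a network state plus its update rules."""

    def __init__(self, state, params):
        self.p = params
        self.w = np.array(state.w, dtype=np.float64)
        self.w_ei = np.array(state.w_ei, dtype=np.float64)
        self.ei_mask = np.array(state.ei_mask, dtype=bool)
        self.w_ie = np.array(state.w_ie, dtype=np.float64)
        self.t_e = np.array(state.t_e, dtype=np.float64)
        self.t_i = np.array(state.t_i, dtype=np.float64)
        self.h_ip = np.array(state.h_ip, dtype=np.float64)
        self.x = np.array(state.x_curr, dtype=np.int64)
        self.x_prev = np.array(state.x_prev, dtype=np.int64)
        self.y = np.array(state.y_curr, dtype=np.int64)
        self.y_prev = np.array(state.y_prev, dtype=np.int64)
        self.n_e = self.w.shape[0]
        self.n_i = self.w_ei.shape[1]

    def step(self, rng, disabled=frozenset()):
        p = self.p
        sigma = math.sqrt(p.noise_var)
        noise_e = rng.normal(0.0, sigma, self.n_e)
        noise_i = rng.normal(0.0, sigma, self.n_i)

        # -- activity -----------------------------------------------------
        x_new = np.zeros(self.n_e, dtype=np.int64)
        for i in range(self.n_e):
            acc = 0.0
            for j in range(self.n_e):
                acc += self.w[i, j] * self.x[j]
            for k in range(self.n_i):
                acc -= self.w_ei[i, k] * self.y[k]
            acc = acc - self.t_e[i] + noise_e[i]
            if acc > 0.0:
                x_new[i] = 1
        y_new = np.zeros(self.n_i, dtype=np.int64)
        for i in range(self.n_i):
            acc = 0.0
            for j in range(self.n_e):
                acc += self.w_ie[i, j] * self.x[j]
            acc = acc - self.t_i[i] + noise_i[i]
            if acc > 0.0:
                y_new[i] = 1
        self.x_prev, self.x = self.x, x_new
        self.y_prev, self.y = self.y, y_new

        # -- STDP with elimination ----------------------------------------
        if "stdp" not in disabled:
            for i in range(self.n_e):
                for j in range(self.n_e):
                    if self.w[i, j] > 0.0:
                        coeff = int(self.x[i]) * int(self.x_prev[j]) \
                            - int(self.x_prev[i]) * int(self.x[j])
                        if coeff != 0:
                            v = self.w[i, j] + p.eta_stdp * coeff
                            self.w[i, j] = 0.0 if v <= 0.0 else v

        # -- inhibitory STDP ----------------------------------------------
        if "istdp" not in disabled:
            gain = 1.0 + 1.0 / p.mu_istdp
            for k in range(self.n_i):
                if self.y_prev[k]:
                    for i in range(self.n_e):
                        if self.ei_mask[i, k]:
                            dv = -p.eta_inhib * (1.0 - self.x[i] * gain)
                            v = self.w_ei[i, k] + dv
                            self.w_ei[i, k] = 0.0 if v < 0.0 else v

        # -- structural plasticity ----------------------------------------
        if "structural" not in disabled:
            n_edges = int(np.count_nonzero(self.w > 0))
            if n_edges < self.n_e * (self.n_e - 1):
                if rng.random() < p.p_struct:
                    pair = None
                    for _ in range(64):
                        i, j = rng.integers(0, self.n_e, size=2)
                        if i != j and self.w[i, j] == 0.0:
                            pair = (int(i), int(j))
                            break
                    if pair is None:
                        cand = [(a, b) for a in range(self.n_e)
                                for b in range(self.n_e)
                                if a != b and self.w[a, b] == 0.0]
                        pair = cand[int(rng.integers(len(cand)))]
                    self.w[pair] = p.w_struct_init

        # -- synaptic scaling ---------------------------------------------
        if "scaling" not in disabled:
            for i in range(self.n_e):
                s = 0.0
                for j in range(self.n_e):
                    s += self.w[i, j]
                if s > 0.0:
                    for j in range(self.n_e):
                        if self.w[i, j] != 0.0:
                            self.w[i, j] = self.w[i, j] / s

        # -- intrinsic plasticity -----------------------------------------
        if "intrinsic" not in disabled:
            for i in range(self.n_e):
                self.t_e[i] = self.t_e[i] + p.eta_ip * (self.x[i]
                                                        - self.h_ip[i])
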