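"""Model parameters for the self-organizing recurrent network (SORN).

A SORN couples a population of ``n_excitatory`` binary threshold neurons to
``n_inhibitory = round(0.2 * n_excitatory)`` inhibitory ones.  Five plasticity
mechanisms act on every time step: causal spike-timing-dependent plasticity
(STDP) on excitatory-to-excitatory synapses, inhibitory STDP on
inhibitory-to-excitatory synapses, multiplicative synaptic scaling of each
excitatory neuron's incoming excitatory weights, intrinsic plasticity of the
excitatory firing thresholds, and stochastic structural plasticity that adds
new weak excitatory synapses.  This module holds every constant those rules
need, with the standard default values.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

__all__ = ["SornParams", "INIT_DISTRIBUTIONS", "default_eta_stdp"]

INIT_DISTRIBUTIONS = ("uniform", "gaussian", "delta", "exponential")

#: (exclusive upper size limit, learning rate) — the STDP learning rate
#: decreases with network size: 0.004 for sizes up to 400, 0.002 for
#: 600-800, 0.001 for 1000 and beyond; sizes falling between two bands use
#: the nearest band below.
_ETA_STDP_BANDS = ((600, 0.004), (1000, 0.002))
_ETA_STDP_LARGE = 0.001


def default_eta_stdp(n_excitatory: int) -> float:
    """Size-dependent STDP learning rate."""
    for upper, eta in _ETA_STDP_BANDS:
        if n_excitatory < upper:
            return eta
    return _ETA_STDP_LARGE


@dataclass
class SornParams:
    """All constants of the SORN model.

    Parameters
    ----------
    n_excitatory
        Number of excitatory neurons (N^E).
    n_inhibitory
        Number of inhibitory neurons.  Derived as ``round(0.2 * n_excitatory)``
        when not given explicitly.
    p_ee_init
        Probability that any ordered excitatory pair starts with a synapse.
    p_ei_init
        Probability that an inhibitory->excitatory synapse exists.  The
        inhibitory->excitatory topology is fixed for the whole simulation.
    p_struct
        Per-step probability that structural plasticity creates one new
        excitatory synapse between a random unconnected pair.
    w_struct_init
        Initial strength of structurally created synapses.
    eta_stdp
        STDP learning rate.  Defaults to the size-dependent value of
        :func:`default_eta_stdp`.
    eta_ip
        Intrinsic-plasticity (threshold adaptation) rate.
    eta_inhib
        Inhibitory STDP learning rate.
    mu_ip
        Mean target firing rate of excitatory neurons (spikes per step).
    sigma_hip
        Half-width of the uniform interval from which per-neuron target
        rates are drawn: ``H_i ~ U[mu_ip - sigma_hip, mu_ip + sigma_hip]``.
    mu_istdp
        Constant of the inhibitory STDP rule; its homeostatic fixed point
        is reached when an excitatory neuron fires with probability
        ``mu_istdp / (1 + mu_istdp)`` after an inhibitory spike.
    t_e_max, t_i_max
        Upper bounds of the uniform initial threshold distributions.  After
        initialization the excitatory thresholds are unbounded.
    noise_var
        Variance of the zero-mean Gaussian membrane noise, for both
        populations.
    init_distribution
        Distribution of the initial excitatory weights before row
        normalization: "uniform", "gaussian" (folded normal), "delta"
        (all equal) or "exponential".
    seed
        RNG seed used when an operation has to create its own generator.
    """

    n_excitatory: int = 200
    n_inhibitory: int | None = None
    p_ee_init: float = 0.1
    p_ei_init: float = 0.2
    p_struct: float = 0.2
    w_struct_init: float = 0.001
    eta_stdp: float | None = None
    eta_ip: float = 0.01
    eta_inhib: float = 0.001
    mu_ip: float = 0.1
    sigma_hip: float = 0.0
    mu_istdp: float = 0.1
    t_e_max: float = 1.0
    t_i_max: float = 0.5
    noise_var: float = 0.01
    init_distribution: str = "uniform"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_excitatory < 2:
            raise ValueError("need at least 2 excitatory neurons")
        derived_ni = int(round(0.2 * self.n_excitatory))
        if self.n_inhibitory is None:
            self.n_inhibitory = max(derived_ni, 1)
        if self.n_inhibitory < 1:
            raise ValueError("need at least 1 inhibitory neuron")
        if self.eta_stdp is None:
            self.eta_stdp = default_eta_stdp(self.n_excitatory)
        for name in ("p_ee_init", "p_ei_init", "p_struct"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        for name in ("eta_stdp", "eta_ip", "eta_inhib", "w_struct_init",
                     "mu_istdp", "t_e_max", "t_i_max"):
            v = getattr(self, name)
            if v <= 0:
                raise ValueError(f"{name}={v} must be > 0")
        if not 0.01 <= self.noise_var <= 0.05:
            raise ValueError(f"noise_var={self.noise_var} outside [0.01, 0.05]")
        if self.sigma_hip < 0:
            raise ValueError("sigma_hip must be >= 0")
        if self.mu_ip <= 0 or self.mu_ip > 1:
            raise ValueError("mu_ip must lie in (0, 1]")
        if self.init_distribution not in INIT_DISTRIBUTIONS:
            raise ValueError(
                f"init_distribution must be one of {INIT_DISTRIBUTIONS}")

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SornParams":
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SornParams":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def replace(self, **kwargs) -> "SornParams":
        """Copy with some fields replaced (re-derives dependent defaults)."""
        d = self.to_dict()
        d.update(kwargs)
        if "n_excitatory" in kwargs:
            if "n_inhibitory" not in kwargs:
                d["n_inhibitory"] = None
            if "eta_stdp" not in kwargs:
                d["eta_stdp"] = None
        return SornParams(**d)
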