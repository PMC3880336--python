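"""Spike-timing-dependent plasticity (STDP).

The rule follows the reference scheme for this network family: when a
postsynaptic spike occurs at time ``t_post`` and a presynaptic spike arrived
at ``t_pre + delay`` (conduction delay included), the weight change is

    lag = t_post - (t_pre + delay)
    lag >= 0:  +A_plus  * exp(-lag / tau_plus)     (potentiation)
    lag <  0:  -A_minus * exp( lag / tau_minus)    (depression)

with nearest-spike pairing (each spike paired with the most recent partner),
deltas accumulated per synapse and applied once per simulated second with
weight clamping to the class bounds.  The optional weight-dependent variant
scales potentiation by (cap - w)/cap and depression by w/cap.

Amplitudes default to the reference values A_plus = 0.1, A_minus = 0.12,
tau = 20 ms.  The per-second additive rate increment the reference scheme
carries is exposed but defaults to 0 (it is removed in the adjusted model
because it overloads a network that receives external input).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

ADDITIVE = "additive"
WEIGHT_DEPENDENT = "weight_dependent"


@dataclass(frozen=True)
class PlasticityParams:
    rule: str = ADDITIVE
    A_plus: float = 0.1
    A_minus: float = 0.12
    tau_plus: float = 20.0
    tau_minus: float = 20.0
    apply_interval_ms: int = 1000
    #: retention factor of the unapplied-delta accumulator at each
    #: application (reference scheme: 0.9).  Past pairings are re-applied
    #: geometrically, so the effective per-pairing amplitude is
    #: A / (1 - retention), ~10x the nominal amplitude at the default.
    accumulator_retention: float = 0.9
    #: additive term per application interval (reference scheme's +0.01/s;
    #: 0 in the adjusted model)
    rate_increment: float = 0.0
    enabled: bool = True

    def __post_init__(self):
        if self.rule not in (ADDITIVE, WEIGHT_DEPENDENT):
            raise ValueError(f"unknown STDP rule {self.rule!r}")
        if self.A_plus < 0 or self.A_minus < 0:
            raise ValueError("STDP amplitudes must be >= 0")
        if self.tau_plus <= 0 or self.tau_minus <= 0:
            raise ValueError("STDP time constants must be > 0")
        if self.apply_interval_ms < 1:
            raise ValueError("apply_interval_ms must be >= 1")

    def disabled(self) -> "PlasticityParams":
        return replace(self, enabled=False)


def stdp_delta(
    pre_spike: float, delay: float, post_spike: float, params: PlasticityParams
) -> float:
    """Weight change for a single pre/post spike pairing.

    ``lag = post_spike - (pre_spike + delay)``; zero lag counts as the
    potentiation boundary (+A_plus).
    """
    lag = post_spike - (pre_spike + delay)
    if lag >= 0:
        return params.A_plus * math.exp(-lag / params.tau_plus)
    return -params.A_minus * math.exp(lag / params.tau_minus)


def stdp_delta_weight_dependent(
    pre_spike: float,
    delay: float,
    post_spike: float,
    weight: float,
    cap: float,
    params: PlasticityParams,
) -> float:
    """Weight-dependent variant: potentiation scaled by the headroom to the
    cap, depression by the distance to zero."""
    base = stdp_delta(pre_spike, delay, post_spike, params)
    if base >= 0:
        return base * (cap - weight) / cap
    return base * weight / cap


def apply_plasticity(network, raster, params: PlasticityParams | None = None):
    """Offline application of STDP for a recorded spike raster.

    Computes nearest-spike pairings per plastic synapse directly from the
    raster with :func:`stdp_delta`, then applies the summed deltas with
    clamping to the class bounds.  This is the closed-form counterpart of
    the online accumulation performed by the simulation engine; it is used
    for analyses and as an independent route in tests.  Non-plastic weights
    are never touched.  Returns ``network`` (modified in place).
    """
    if params is None:
        params = network.plasticity
    if not params.enabled:
        return network
    syn = network.syn
    spikes_of: dict[int, np.ndarray] = {}
    for n in np.unique(raster.neurons):
        spikes_of[int(n)] = np.sort(raster.times[raster.neurons == n])
    delta = np.zeros(syn.weight.shape[0])
    for s in np.flatnonzero(syn.plastic):
        pre_t = spikes_of.get(int(syn.pre[s]))
        post_t = spikes_of.get(int(syn.post[s]))
        if pre_t is None or post_t is None:
            continue
        arrivals = pre_t + syn.delay[s]
        # potentiation: each post spike paired with the latest arrival <= it
        k = np.searchsorted(arrivals, post_t, side="right") - 1
        ok = k >= 0
        for q, ki in zip(post_t[ok], k[ok]):
            d = stdp_delta(arrivals[ki] - syn.delay[s], syn.delay[s], q, params)
            if params.rule == WEIGHT_DEPENDENT:
                d *= (syn.cap[s] - syn.weight[s]) / syn.cap[s]
            delta[s] += d
        # depression: each arrival paired with the latest post spike < it
        k = np.searchsorted(post_t, arrivals, side="left") - 1
        ok = k >= 0
        for a, ki in zip(arrivals[ok], k[ok]):
            d = stdp_delta(a - syn.delay[s], syn.delay[s], post_t[ki], params)
            if d < 0:
                if params.rule == WEIGHT_DEPENDENT:
                    d *= syn.weight[s] / syn.cap[s]
                delta[s] += d
    plastic = syn.plastic
    syn.weight[plastic] = np.clip(
        syn.weight[plastic] + delta[plastic], 0.0, syn.cap[plastic]
    )
    return network
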