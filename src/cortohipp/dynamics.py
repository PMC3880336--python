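"""Izhikevich point-neuron dynamics.

The membrane model is the two-variable quadratic integrate-and-fire
approximation

    dv/dt = 0.04 v^2 + 5 v + 140 - u + I
    du/dt = a (b v - u)

with the after-spike reset v <- r1, u <- u + r2 once v crosses the 30 mV
threshold.  Integration is forward Euler with a 0.5 ms step; input currents
are delivered on a 1 ms grid and held constant over both half-steps of the
delivery millisecond, matching the reference integration scheme this model
family is normally simulated with.

Note that the regular-spiking preset has its stable equilibrium at
(v, u) = (-70, -14), not at the reset point (-65, -13): an unstimulated
neuron relaxes to the former.  "Rest" throughout this package means that
stable fixed point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

SPIKE_THRESHOLD_MV = 30.0
DEFAULT_DT_MS = 0.5


class IntegrationBlowupError(RuntimeError):
    """Membrane state became non-finite during integration."""

    def __init__(self, neuron: int):
        self.neuron = int(neuron)
        super().__init__(f"non-finite membrane state in neuron {neuron}")


@dataclass(frozen=True)
class NeuronParams:
    """Parameters of one Izhikevich neuron.

    a : recovery time scale (1/ms)
    b : recovery sensitivity (dimensionless)
    r1: after-spike reset potential (mV)
    r2: after-spike recovery increment
    """

    a: float
    b: float
    r1: float
    r2: float

    def __post_init__(self):
        for name in ("a", "b", "r1", "r2"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"NeuronParams.{name} must be finite")

    def resting_state(self) -> tuple[float, float]:
        """Stable fixed point (v*, u*) of the subthreshold dynamics.

        Solves 0.04 v^2 + 5 v + 140 - b v = 0 and returns the
        lower (stable) root together with u* = b v*.
        """
        disc = (5.0 - self.b) ** 2 - 4 * 0.04 * 140.0
        if disc < 0:
            raise ValueError("preset has no subthreshold fixed point")
        v = (-(5.0 - self.b) - math.sqrt(disc)) / (2 * 0.04)
        return v, self.b * v


#: Regular-spiking preset used for excitatory (cortical and hippocampal) neurons.
EXCITATORY = NeuronParams(a=0.02, b=0.2, r1=-65.0, r2=8.0)
#: Fast-spiking preset used for inhibitory cortical neurons.
INHIBITORY = NeuronParams(a=0.1, b=0.2, r1=-65.0, r2=2.0)


class NeuronPopulationState:
    """Vectorised membrane state (v, u) for a heterogeneous population."""

    __slots__ = ("v", "u", "a", "b", "r1", "r2")

    def __init__(self, params: list[NeuronParams] | NeuronParams, n: int | None = None):
        if isinstance(params, NeuronParams):
            if n is None:
                raise ValueError("n required when a single preset is given")
            params = [params] * n
        self.a = np.array([p.a for p in params], dtype=float)
        self.b = np.array([p.b for p in params], dtype=float)
        self.r1 = np.array([p.r1 for p in params], dtype=float)
        self.r2 = np.array([p.r2 for p in params], dtype=float)
        self.v = np.empty(len(params), dtype=float)
        self.u = np.empty(len(params), dtype=float)
        for i, p in enumerate(params):
            self.v[i], self.u[i] = p.resting_state()

    def __len__(self) -> int:
        return self.v.shape[0]

    def copy(self) -> "NeuronPopulationState":
        out = object.__new__(NeuronPopulationState)
        for name in self.__slots__:
            setattr(out, name, getattr(self, name).copy())
        return out


def _half_step(v, u, a, b, I, dt):
    v += dt * (0.04 * v * v + 5.0 * v + 140.0 - u + I)
    u += dt * (a * (b * v - u))


def step_population(
    state: NeuronPopulationState,
    I: np.ndarray,
    dt: float = DEFAULT_DT_MS,
) -> np.ndarray:
    """Advance the population by one Euler step of length ``dt``.

    Neurons already at or above threshold on entry are reported as spiked
    and reset without being integrated.  Neurons crossing threshold during
    the step are clamped to the threshold (bounding recorded spike
    waveforms), reported, and reset.  Returns the array of spiked neuron
    ids; mutates ``state`` in place.
    """
    v, u = state.v, state.u
    pre_spiked = v >= SPIKE_THRESHOLD_MV
    alive = ~pre_spiked
    if alive.all():
        _half_step(v, u, state.a, state.b, I, dt)
    else:
        va, ua = v[alive], u[alive]
        _half_step(va, ua, state.a[alive], state.b[alive], np.asarray(I)[alive], dt)
        v[alive], u[alive] = va, ua
    crossed = (v >= SPIKE_THRESHOLD_MV) & alive
    v[crossed] = SPIKE_THRESHOLD_MV
    spiked = np.flatnonzero(pre_spiked | crossed)
    if spiked.size:
        v[spiked] = state.r1[spiked]
        u[spiked] += state.r2[spiked]
    bad = ~(np.isfinite(v) & np.isfinite(u))
    if bad.any():
        raise IntegrationBlowupError(np.flatnonzero(bad)[0])
    return spiked


UNREACHABLE = None  # sentinel returned when no input count can elicit a spike


def _spike_latency(
    params: NeuronParams, current: float, horizon_ms: float, dt: float = DEFAULT_DT_MS
) -> float | None:
    """Latency (ms) of the first spike of a rested neuron receiving
    ``current`` mV for 1 ms at t=0, or None if it stays silent."""
    state = NeuronPopulationState([params])
    steps_per_ms = max(1, round(1.0 / dt))
    t = 0.0
    while t < horizon_ms:
        I = np.array([current if t < 1.0 else 0.0])
        for k in range(steps_per_ms):
            if step_population(state, I, dt).size:
                return t + (k + 1) * dt
        t += 1.0
    return None


def find_min_inputs_to_spike(
    params: NeuronParams = EXCITATORY,
    unit_weight: float = 5.0,
    horizon_ms: float = 50.0,
    max_inputs: int = 50,
) -> int | None:
    """Smallest number of simultaneous ``unit_weight`` mV inputs that makes a
    rested neuron spike within ``horizon_ms``; ``UNREACHABLE`` (None) if no
    count up to ``max_inputs`` does."""
    for k in range(1, max_inputs + 1):
        if _spike_latency(params, k * unit_weight, horizon_ms) is not None:
            return k
    return UNREACHABLE


def min_current_to_spike(
    params: NeuronParams = EXCITATORY,
    horizon_ms: float = 50.0,
    tol: float = 0.1,
) -> float:
    """Minimal 1 ms current pulse (mV) that fires a rested neuron, by
    bisection.  Used to decide whether a set of synaptic inputs can account
    for a spike on its own."""
    lo, hi = 0.0, 40.0
    if _spike_latency(params, hi, horizon_ms) is None:
        raise ValueError("upper bracket does not elicit a spike")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _spike_latency(params, mid, horizon_ms) is None:
            lo = mid
        else:
            hi = mid
    return hi
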