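"""Network construction and simulation.

The cortex is the classic 1000-neuron network: 800 excitatory and 200
inhibitory neurons, each with 100 outgoing synapses to distinct random
cortical targets (inhibitory neurons target excitatory neurons only),
excitatory conduction delays integer-uniform in 1-20 ms, inhibitory delays
1 ms.  Initial weights are +1 mV (excitatory) and -5 mV (inhibitory).
The excitatory baseline is a calibrated parameter of no interest: it is set
low enough that a synchronized 50-neuron volley recruits almost no
secondary spikes (no reaction chain, the basic stability requirement every
experiment assumes) while plastic pathways can still grow to the 10 mV cap
during learning.

The hippocampal loop attaches h input and h output neurons.  Each input
neuron receives c non-plastic forward synapses from randomly selected
cortical neurons; inputs relay one-to-one to outputs through a strong
fixed synapse; each output neuron sends c plastic backprojections to random
excitatory cortical neurons.  Delays are either uniform (d forward, 1 ms
relay, d backward) or dispersed (forward/backward 1-5 ms, relay 10-90 ms),
so a synchronous cortical volley returns over a 12-100 ms window in the
dispersion variant.

The engine integrates the whole network on a 1 ms event grid with two
0.5 ms Euler half-steps per tick, propagates spikes through a ring delay
buffer, and accumulates STDP online (trace-based nearest-spike pairing,
applied once per simulated second).
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field, replace

import numpy as np

from .dynamics import (
    EXCITATORY,
    INHIBITORY,
    SPIKE_THRESHOLD_MV,
    IntegrationBlowupError,
    NeuronParams,
    NeuronPopulationState,
)
from .plasticity import WEIGHT_DEPENDENT, PlasticityParams

N_CTX = 1000
N_EXC = 800
N_INH = 200
CTX_OUT_DEGREE = 100
CTX_EXC_WEIGHT = 1.0
#: the reference model's uniform initial excitatory weight, used by the
#: unadjusted parameter set
CTX_EXC_WEIGHT_REFERENCE = 6.0
CTX_INH_WEIGHT = -5.0
CTX_EXC_WEIGHT_CAP = 10.0
CTX_EXC_DELAY_RANGE = (1, 20)
INH_DELAY_MS = 1
RELAY_DELAY_MS = 1  # uniform-delay variant

# connection classes
CLS_CTX_EXC = 0  # ctx_exc -> ctx            (plastic, cap 10 mV)
CLS_CTX_INH = 1  # ctx_inh -> ctx_exc        (fixed -5 mV)
CLS_CTX_HIPP = 2  # ctx -> hipp_in           (fixed forward projection)
CLS_RELAY = 3  # hipp_in_i -> hipp_out_i     (fixed, strong)
CLS_HIPP_CTX = 4  # hipp_out -> ctx_exc      (plastic, cap 5 mV)

CLS_NAMES = {
    CLS_CTX_EXC: "ctx_exc->ctx",
    CLS_CTX_INH: "ctx_inh->ctx_exc",
    CLS_CTX_HIPP: "ctx->hipp_in",
    CLS_RELAY: "hipp_relay",
    CLS_HIPP_CTX: "hipp_out->ctx_exc",
}

NOISE_AMPLITUDE_MV = 20.0
OVERLOAD_FRACTION = 0.9
OVERLOAD_SUSTAIN_MS = 500


class ConfigurationError(ValueError):
    pass


@dataclass
class LoopConfig:
    """Parameters of the hippocampal loop and its surrounding conditions.

    h : number of hippocampal input (= output) neurons
    c : connections per hippocampal neuron (forward and backward)
    d : uniform cortex<->hippocampus conduction delay (ms); mutually
        exclusive with ``dispersion``
    dispersion : if True, cortex<->hippocampus delays are integer-uniform in
        ``ctx_hipp_delay_range`` and relay delays in ``relay_delay_range``
    """

    h: int = 100
    c: int = 300
    d: int | None = 50
    dispersion: bool = False
    ctx_hipp_delay_range: tuple[int, int] = (1, 5)
    relay_delay_range: tuple[int, int] = (10, 90)
    noise_rate_hz: float = 100.0
    #: calibrated so a synchronized 50-neuron volley recruits 30-50
    #: hippocampal input neurons (~0.9 mV, i.e. an average of roughly 1 mV)
    forward_weight_mean: float = 0.9
    forward_weight_halfwidth: float = 0.5
    #: population the forward projections sample from ("ctx_exc" or "ctx")
    forward_source: str = "ctx_exc"
    back_weight_init: float = 0.1
    back_weight_cap: float = 5.0
    relay_weight: float = 30.0
    #: initial cortical excitatory weight the cortex is built with
    ctx_exc_weight: float = CTX_EXC_WEIGHT

    def __post_init__(self):
        if self.h < 0:
            raise ConfigurationError("h must be >= 0")
        if self.h > 0 and self.c < 1:
            raise ConfigurationError("c must be >= 1 when h > 0")
        if (self.d is None) == (not self.dispersion):
            raise ConfigurationError(
                "exactly one of uniform delay d / dispersion must be set"
            )
        if self.noise_rate_hz < 0:
            raise ConfigurationError("noise_rate_hz must be >= 0")
        if self.forward_source not in ("ctx_exc", "ctx"):
            raise ConfigurationError("forward_source must be 'ctx_exc' or 'ctx'")

    @staticmethod
    def unadjusted(h: int = 100, c: int = 300, d: int | None = 50, **kw) -> "LoopConfig":
        """Reference-model settings before the stabilising adjustments:
        forward weights 6 mV, backprojection weights 6 mV capped at 10 mV,
        1000 Hz thalamic noise."""
        return LoopConfig(
            h=h,
            c=c,
            d=d,
            noise_rate_hz=1000.0,
            forward_weight_mean=CTX_EXC_WEIGHT_REFERENCE,
            forward_weight_halfwidth=0.0,
            back_weight_init=CTX_EXC_WEIGHT_REFERENCE,
            back_weight_cap=CTX_EXC_WEIGHT_CAP,
            ctx_exc_weight=CTX_EXC_WEIGHT_REFERENCE,
            **kw,
        )

    def loop_delay_bounds(self) -> tuple[int, int]:
        """Minimal and maximal total cortex->cortex delay through the loop."""
        if self.dispersion:
            f0, f1 = self.ctx_hipp_delay_range
            r0, r1 = self.relay_delay_range
            return 2 * f0 + r0, 2 * f1 + r1
        return 2 * self.d + RELAY_DELAY_MS, 2 * self.d + RELAY_DELAY_MS


@dataclass
class SynapseTable:
    """Flat per-connection arrays, sorted by presynaptic neuron."""

    pre: np.ndarray  # int32
    post: np.ndarray  # int32
    weight: np.ndarray  # float64, mV
    delay: np.ndarray  # int16, ms (>= 1)
    plastic: np.ndarray  # bool
    cls: np.ndarray  # int8
    cap: np.ndarray  # float64, clamp upper bound per synapse

    def __len__(self):
        return self.pre.shape[0]

    def copy(self) -> "SynapseTable":
        return SynapseTable(*(getattr(self, f).copy() for f in
                              ("pre", "post", "weight", "delay", "plastic", "cls", "cap")))


@dataclass
class StimulusSchedule:
    """External currents: at tick ``time_ms`` neuron ``neuron`` receives
    ``amp`` mV for 1 ms."""

    time_ms: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    neuron: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    amp: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=float))

    def __len__(self):
        return self.time_ms.shape[0]

    @staticmethod
    def merge(*schedules: "StimulusSchedule") -> "StimulusSchedule":
        schedules = [s for s in schedules if s is not None and len(s)]
        if not schedules:
            return StimulusSchedule()
        t = np.concatenate([s.time_ms for s in schedules])
        n = np.concatenate([s.neuron for s in schedules])
        a = np.concatenate([s.amp for s in schedules])
        order = np.argsort(t, kind="stable")
        return StimulusSchedule(t[order], n[order], a[order])

    def shifted(self, dt_ms: int) -> "StimulusSchedule":
        return StimulusSchedule(self.time_ms + dt_ms, self.neuron, self.amp)


@dataclass
class SpikeRaster:
    """Ordered spike events plus population partition labels."""

    times: np.ndarray
    neurons: np.ndarray
    partitions: dict[str, tuple[int, int]]
    overload: bool = False

    def __len__(self):
        return self.times.shape[0]

    def select(self, label: str) -> "SpikeRaster":
        lo, hi = self.partitions[label]
        m = (self.neurons >= lo) & (self.neurons < hi)
        return SpikeRaster(self.times[m], self.neurons[m], self.partitions, self.overload)

    def window(self, t0: float, t1: float) -> "SpikeRaster":
        m = (self.times >= t0) & (self.times < t1)
        return SpikeRaster(self.times[m], self.neurons[m], self.partitions, self.overload)


def partition_labels(h: int) -> dict[str, tuple[int, int]]:
    parts = {"ctx_exc": (0, N_EXC), "ctx_inh": (N_EXC, N_CTX)}
    if h:
        parts["hipp_in"] = (N_CTX, N_CTX + h)
        parts["hipp_out"] = (N_CTX + h, N_CTX + 2 * h)
    return parts


class Network:
    """Mutable simulation state: neurons, synapses, plasticity accumulator.

    ``run`` advances the membrane state and (when plasticity is enabled)
    the weights in place, so successive calls continue the same network.
    """

    def __init__(
        self,
        state: NeuronPopulationState,
        syn: SynapseTable,
        cfg: LoopConfig | None,
        plasticity: PlasticityParams | None = None,
    ):
        self.state = state
        self.syn = syn
        self.cfg = cfg
        self.plasticity = plasticity or PlasticityParams()
        self.h = cfg.h if cfg is not None else 0
        self.sd = np.zeros(len(syn))  # accumulated, not-yet-applied deltas
        self.ms_since_apply = 0
        self.overload = False
        self._lesion_backup = None
        self._compile()

    # -- structure ---------------------------------------------------------
    def _compile(self):
        syn = self.syn
        n = len(self.state)
        order = np.argsort(syn.pre, kind="stable")
        for f in ("pre", "post", "weight", "delay", "plastic", "cls", "cap"):
            setattr(syn, f, getattr(syn, f)[order])
        self.out_ptr = np.zeros(n + 1, dtype=np.int64)
        np.cumsum(np.bincount(syn.pre, minlength=n), out=self.out_ptr[1:])
        # incoming plastic synapses grouped by postsynaptic neuron
        pl = np.flatnonzero(syn.plastic)
        by_post = pl[np.argsort(syn.post[pl], kind="stable")]
        self.in_syn = by_post
        self.in_ptr = np.zeros(n + 1, dtype=np.int64)
        np.cumsum(np.bincount(syn.post[pl], minlength=n), out=self.in_ptr[1:])
        self.max_delay = int(syn.delay.max(initial=1))

    @property
    def n_neurons(self) -> int:
        return len(self.state)

    @property
    def partitions(self) -> dict[str, tuple[int, int]]:
        return partition_labels(self.h)

    def copy(self) -> "Network":
        out = object.__new__(Network)
        out.state = self.state.copy()
        out.syn = self.syn.copy()
        out.cfg = _copy.deepcopy(self.cfg)
        out.plasticity = self.plasticity
        out.h = self.h
        out.sd = self.sd.copy()
        out.ms_since_apply = self.ms_since_apply
        out.overload = self.overload
        out._lesion_backup = _copy.deepcopy(self._lesion_backup)
        out.out_ptr = self.out_ptr
        out.in_syn = self.in_syn
        out.in_ptr = self.in_ptr
        out.max_delay = self.max_delay
        return out

    # -- lesioning ---------------------------------------------------------
    def lesion_hippocampus(self) -> "Network":
        """Zero the cortex->hippocampus forward weights and disable STDP.

        Reversible through :meth:`unlesion_hippocampus`."""
        if self.h == 0:
            raise ConfigurationError("network has no hippocampal loop")
        if self._lesion_backup is not None:
            return self
        fwd = self.syn.cls == CLS_CTX_HIPP
        self._lesion_backup = (self.syn.weight[fwd].copy(), self.plasticity)
        self.syn.weight[fwd] = 0.0
        self.plasticity = self.plasticity.disabled()
        return self

    def unlesion_hippocampus(self) -> "Network":
        if self._lesion_backup is None:
            return self
        weights, plast = self._lesion_backup
        self.syn.weight[self.syn.cls == CLS_CTX_HIPP] = weights
        self.plasticity = plast
        self._lesion_backup = None
        return self

    # -- simulation --------------------------------------------------------
    def run(
        self,
        duration_ms: int,
        stimuli: StimulusSchedule | None = None,
        seed: int | None = 0,
        plasticity: bool | None = None,
        record: str | tuple[str, ...] = "all",
        noise_rate_hz: float | None = None,
    ) -> SpikeRaster:
        return _run(self, duration_ms, stimuli, seed, plasticity, record, noise_rate_hz)


def build_cortex(
    seed: int = 0,
    plasticity: PlasticityParams | None = None,
    exc_weight: float = CTX_EXC_WEIGHT,
) -> Network:
    """The 1000-neuron cortical network with seeded random wiring."""
    rng = np.random.default_rng(seed)
    params = [EXCITATORY] * N_EXC + [INHIBITORY] * N_INH
    state = NeuronPopulationState(params)
    pre = np.repeat(np.arange(N_CTX, dtype=np.int32), CTX_OUT_DEGREE)
    post = np.empty(N_CTX * CTX_OUT_DEGREE, dtype=np.int32)
    for i in range(N_CTX):
        if i < N_EXC:
            targets = rng.choice(N_CTX - 1, size=CTX_OUT_DEGREE, replace=False)
            targets[targets >= i] += 1  # distinct targets, no self-connection
        else:  # inhibitory neurons target excitatory neurons only
            targets = rng.choice(N_EXC, size=CTX_OUT_DEGREE, replace=False)
        post[i * CTX_OUT_DEGREE : (i + 1) * CTX_OUT_DEGREE] = targets
    exc = pre < N_EXC
    weight = np.where(exc, exc_weight, CTX_INH_WEIGHT).astype(float)
    delay = np.where(
        exc,
        rng.integers(CTX_EXC_DELAY_RANGE[0], CTX_EXC_DELAY_RANGE[1] + 1, size=pre.shape),
        INH_DELAY_MS,
    ).astype(np.int16)
    cls = np.where(exc, CLS_CTX_EXC, CLS_CTX_INH).astype(np.int8)
    cap = np.full(pre.shape, CTX_EXC_WEIGHT_CAP)
    syn = SynapseTable(pre, post, weight, delay, exc.copy(), cls, cap)
    return Network(state, syn, cfg=None, plasticity=plasticity)


def attach_hippocampus(cortex: Network, cfg: LoopConfig, seed: int = 0) -> Network:
    """Attach the hippocampal input/output loop to a cortical network.

    Returns a new :class:`Network`; the cortex argument is not modified.
    """
    if cortex.h:
        raise ConfigurationError("network already has a hippocampal loop")
    h, c = cfg.h, cfg.c
    if h == 0:
        net = cortex.copy()
        net.cfg = replace(cfg)
        return net
    if c > N_CTX:
        raise ConfigurationError(f"c={c} exceeds the {N_CTX} available cortical sources")
    rng = np.random.default_rng(seed)
    state = NeuronPopulationState([EXCITATORY] * (N_CTX + 2 * h))
    state.v[:N_CTX] = cortex.state.v
    state.u[:N_CTX] = cortex.state.u
    state.a[:N_CTX] = cortex.state.a
    state.b[:N_CTX] = cortex.state.b
    state.r1[:N_CTX] = cortex.state.r1
    state.r2[:N_CTX] = cortex.state.r2

    hin = np.arange(N_CTX, N_CTX + h, dtype=np.int32)
    hout = hin + h

    # forward: c connections from randomly selected cortical neurons per input
    fwd_pool = N_EXC if cfg.forward_source == "ctx_exc" else N_CTX
    if c > fwd_pool:
        raise ConfigurationError(f"c={c} exceeds the {fwd_pool} forward sources")
    f_pre = np.empty(h * c, dtype=np.int32)
    for i in range(h):
        f_pre[i * c : (i + 1) * c] = rng.choice(fwd_pool, size=c, replace=False)
    f_post = np.repeat(hin, c)
    lo = cfg.forward_weight_mean - cfg.forward_weight_halfwidth
    hi = cfg.forward_weight_mean + cfg.forward_weight_halfwidth
    f_w = rng.uniform(lo, hi, size=h * c) if hi > lo else np.full(h * c, lo)
    if cfg.dispersion:
        f_d = rng.integers(cfg.ctx_hipp_delay_range[0], cfg.ctx_hipp_delay_range[1] + 1,
                           size=h * c)
    else:
        f_d = np.full(h * c, cfg.d)

    # relay: one-to-one, strong and fixed
    if cfg.dispersion:
        r_d = rng.integers(cfg.relay_delay_range[0], cfg.relay_delay_range[1] + 1, size=h)
    else:
        r_d = np.full(h, RELAY_DELAY_MS)

    # backprojections: c plastic connections to random excitatory targets
    b_pre = np.repeat(hout, c)
    b_post = np.empty(h * c, dtype=np.int32)
    if c > N_EXC:
        raise ConfigurationError(
            f"c={c} exceeds the {N_EXC} available excitatory targets")
    for i in range(h):
        b_post[i * c : (i + 1) * c] = rng.choice(N_EXC, size=c, replace=False)
    if cfg.dispersion:
        b_d = rng.integers(cfg.ctx_hipp_delay_range[0], cfg.ctx_hipp_delay_range[1] + 1,
                           size=h * c)
    else:
        b_d = np.full(h * c, cfg.d)

    csyn = cortex.syn
    syn = SynapseTable(
        pre=np.concatenate([csyn.pre, f_pre, hin, b_pre]).astype(np.int32),
        post=np.concatenate([csyn.post, f_post, hout, b_post]).astype(np.int32),
        weight=np.concatenate(
            [csyn.weight, f_w, np.full(h, cfg.relay_weight),
             np.full(h * c, cfg.back_weight_init)]),
        delay=np.concatenate([csyn.delay, f_d, r_d, b_d]).astype(np.int16),
        plastic=np.concatenate(
            [csyn.plastic, np.zeros(h * c, bool), np.zeros(h, bool),
             np.ones(h * c, bool)]),
        cls=np.concatenate(
            [csyn.cls, np.full(h * c, CLS_CTX_HIPP), np.full(h, CLS_RELAY),
             np.full(h * c, CLS_HIPP_CTX)]).astype(np.int8),
        cap=np.concatenate(
            [csyn.cap, np.full(h * c, np.inf), np.full(h, np.inf),
             np.full(h * c, cfg.back_weight_cap)]),
    )
    return Network(state, syn, cfg=replace(cfg), plasticity=cortex.plasticity)


def thalamic_noise(
    rate_hz: float, duration_ms: int, seed: int, n_targets: int = N_CTX
) -> StimulusSchedule:
    """Thalamic drive: every 1000/rate ms one uniformly chosen *cortical*
    neuron receives a 20 mV current (hippocampal neurons get none)."""
    if rate_hz <= 0:
        return StimulusSchedule()
    interval = max(1, round(1000.0 / rate_hz))
    times = np.arange(0, duration_ms, interval, dtype=np.int64)
    rng = np.random.default_rng(seed)
    neurons = rng.integers(0, n_targets, size=times.shape[0])
    return StimulusSchedule(times, neurons, np.full(times.shape[0], NOISE_AMPLITUDE_MV))


def lesion_hippocampus(network: Network) -> Network:
    return network.lesion_hippocampus()


def unlesion_hippocampus(network: Network) -> Network:
    return network.unlesion_hippocampus()


# ---------------------------------------------------------------------------
# engine


def _run(
    net: Network,
    duration_ms: int,
    stimuli: StimulusSchedule | None,
    seed: int | None,
    plasticity: bool | None,
    record,
    noise_rate_hz: float | None,
) -> SpikeRaster:
    state, syn = net.state, net.syn
    n = len(state)
    v, u = state.v, state.u
    a_par, b_par, r1, r2 = state.a, state.b, state.r1, state.r2
    pp = net.plasticity
    plast_on = pp.enabled if plasticity is None else (plasticity and pp.enabled)
    wdep = pp.rule == WEIGHT_DEPENDENT

    if noise_rate_hz is None:
        noise_rate_hz = net.cfg.noise_rate_hz if net.cfg is not None else 0.0
    noise = thalamic_noise(noise_rate_hz, duration_ms, seed if seed is not None else 0)
    stim = StimulusSchedule.merge(noise, stimuli)
    st_t, st_n, st_a = stim.time_ms, stim.neuron, stim.amp
    sp, n_stim = 0, len(stim)

    H = max(net.max_delay + 1, 2)
    arrivals: list[list[np.ndarray]] = [[] for _ in range(H)]
    hist_p = np.zeros((H, n))
    trace_p = np.zeros(n)
    trace_m = np.zeros(n)
    decay_p = float(np.exp(-1.0 / pp.tau_plus))
    decay_m = float(np.exp(-1.0 / pp.tau_minus))
    sd = net.sd
    plastic_idx = np.flatnonzero(syn.plastic)

    pre_arr, post_arr, w_arr, d_arr = syn.pre, syn.post, syn.weight, syn.delay
    pl_arr, cap_arr = syn.plastic, syn.cap
    out_ptr, in_ptr, in_syn = net.out_ptr, net.in_ptr, net.in_syn

    rec_times: list[float] = []
    rec_ids: list[np.ndarray] = []
    I = np.zeros(n)
    overload_streak = 0
    overload = False
    overload_thresh = OVERLOAD_FRACTION * n

    for t in range(int(duration_ms)):
        slot = t % H
        I[:] = 0.0
        bucket = arrivals[slot]
        if bucket:
            idx = bucket[0] if len(bucket) == 1 else np.concatenate(bucket)
            arrivals[slot] = []
            np.add.at(I, post_arr[idx], w_arr[idx])
            if plast_on:
                pidx = idx[pl_arr[idx]]
                if pidx.size:
                    dep = trace_m[post_arr[pidx]]
                    if wdep:
                        dep = dep * (w_arr[pidx] / cap_arr[pidx])
                    sd[pidx] -= dep
        while sp < n_stim and st_t[sp] == t:
            I[st_n[sp]] += st_a[sp]
            sp += 1

        # two 0.5 ms Euler half-steps; input held over both
        fired_mask = None
        for _half in range(2):
            if fired_mask is None:
                v += 0.5 * (v * (0.04 * v + 5.0) + 140.0 - u + I)
                u += 0.5 * (a_par * (b_par * v - u))
                crossed = v >= SPIKE_THRESHOLD_MV
                if crossed.any():
                    v[crossed] = SPIKE_THRESHOLD_MV
                    fired_mask = crossed
            else:
                act = ~fired_mask
                dv = 0.5 * (v * (0.04 * v + 5.0) + 140.0 - u + I)
                v[act] += dv[act]
                du = 0.5 * (a_par * (b_par * v - u))
                u[act] += du[act]
                crossed = (v >= SPIKE_THRESHOLD_MV) & act
                if crossed.any():
                    v[crossed] = SPIKE_THRESHOLD_MV
                    fired_mask |= crossed

        if fired_mask is not None:
            fired = np.flatnonzero(fired_mask)
            rec_times.append(float(t))
            rec_ids.append(fired.astype(np.int32))
            v[fired] = r1[fired]
            u[fired] += r2[fired]
            if plast_on:
                chunks = [in_syn[in_ptr[j] : in_ptr[j + 1]] for j in fired]
                sidx = chunks[0] if len(chunks) == 1 else np.concatenate(chunks)
                if sidx.size:
                    val = hist_p[(t - d_arr[sidx].astype(np.int64)) % H, pre_arr[sidx]]
                    if wdep:
                        val = val * ((cap_arr[sidx] - w_arr[sidx]) / cap_arr[sidx])
                    sd[sidx] += val
                trace_p[fired] = pp.A_plus
                trace_m[fired] = pp.A_minus
            # schedule deliveries
            for j in fired:
                s0, s1 = out_ptr[j], out_ptr[j + 1]
                if s0 == s1:
                    continue
                sl = (t + d_arr[s0:s1].astype(np.int64)) % H
                uniq, inv = np.unique(sl, return_inverse=True)
                base = np.arange(s0, s1)
                for k, s_ in enumerate(uniq):
                    arrivals[s_].append(base[inv == k])
            if fired.size > overload_thresh:
                overload_streak += 1
                if overload_streak > OVERLOAD_SUSTAIN_MS:
                    overload = True
            else:
                overload_streak = 0

        hist_p[slot, :] = trace_p
        trace_p *= decay_p
        trace_m *= decay_m

        net.ms_since_apply += 1
        if plast_on and net.ms_since_apply >= pp.apply_interval_ms:
            net.ms_since_apply = 0
            w_arr[plastic_idx] = np.clip(
                w_arr[plastic_idx] + sd[plastic_idx] + pp.rate_increment,
                0.0,
                cap_arr[plastic_idx],
            )
            sd[plastic_idx] *= pp.accumulator_retention

        if t % 200 == 199 and not np.isfinite(v).all():
            raise IntegrationBlowupError(np.flatnonzero(~np.isfinite(v))[0])

    if not (np.isfinite(v).all() and np.isfinite(u).all()):
        bad = ~(np.isfinite(v) & np.isfinite(u))
        raise IntegrationBlowupError(np.flatnonzero(bad)[0])

    if rec_ids:
        times = np.concatenate(
            [np.full(ids.shape[0], tt) for tt, ids in zip(rec_times, rec_ids)]
        )
        neurons = np.concatenate(rec_ids)
    else:
        times = np.empty(0)
        neurons = np.empty(0, dtype=np.int32)
    net.overload = net.overload or overload
    raster = SpikeRaster(times, neurons, net.partitions, overload)
    if record != "all":
        labels = (record,) if isinstance(record, str) else tuple(record)
        mask = np.zeros(len(raster), dtype=bool)
        for lab in labels:
            lo, hi = raster.partitions[lab]
            mask |= (neurons >= lo) & (neurons < hi)
        raster = SpikeRaster(times[mask], neurons[mask], raster.partitions, overload)
    return raster
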