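import numpy as np
import pytest

import cortohipp as ch
from cortohipp.circuit import (
    CLS_CTX_EXC,
    CLS_CTX_HIPP,
    CLS_CTX_INH,
    CLS_HIPP_CTX,
    CLS_RELAY,
    N_CTX,
    N_EXC,
    ConfigurationError,
    LoopConfig,
    StimulusSchedule,
    build_cortex,
    thalamic_noise,
)

# -- construction ------------------------------------------------------------


def test_cortex_composition():
    net = build_cortex(seed=1)
    syn = net.syn
    assert len(syn) == N_CTX * 100
    out_deg = np.bincount(syn.pre, minlength=N_CTX)
    assert (out_deg == 100).all()
    inh = syn.pre >= N_EXC
    assert (syn.post[inh] < N_EXC).all()  # inhibitory target excitatory only
    assert (syn.weight[inh] == -5.0).all()
    assert (syn.delay[inh] == 1).all()
    exc = ~inh
    assert syn.delay[exc].min() >= 1 and syn.delay[exc].max() <= 20
    assert (syn.pre != syn.post).all()
    assert syn.plastic[exc].all() and not syn.plastic[inh].any()


def test_cortex_build_is_deterministic():
    a, b = build_cortex(seed=7), build_cortex(seed=7)
    assert (a.syn.post == b.syn.post).all()
    assert (a.syn.delay == b.syn.delay).all()
    c = build_cortex(seed=8)
    assert (a.syn.post != c.syn.post).any()


def test_attach_hippocampus_arithmetic():
    cfg = LoopConfig(h=100, c=300, d=50)
    net = ch.make_network(cfg, seed=2)
    syn = net.syn
    assert net.n_neurons == N_CTX + 200
    assert (syn.cls == CLS_CTX_HIPP).sum() == 30_000
    assert (syn.cls == CLS_HIPP_CTX).sum() == 30_000
    assert (syn.cls == CLS_RELAY).sum() == 100
    # class invariants
    back = syn.cls == CLS_HIPP_CTX
    assert syn.plastic[back].all()
    assert (syn.cap[back] == 5.0).all()
    assert (syn.post[back] < N_EXC).all()
    fwd = syn.cls == CLS_CTX_HIPP
    assert not syn.plastic[fwd].any()
    assert (syn.delay[fwd] == 50).all()
    relay = syn.cls == CLS_RELAY
    assert (syn.post[relay] - syn.pre[relay] == 100).all()  # one per input neuron


def test_attach_h0_reduces_to_cortex():
    net = ch.make_network(LoopConfig(h=0, c=300, d=50), seed=2)
    assert net.n_neurons == N_CTX
    assert len(net.syn) == N_CTX * 100
    assert "hipp_in" not in net.partitions


def test_attach_rejects_oversized_c():
    cortex = build_cortex(seed=0)
    with pytest.raises(ConfigurationError):
        ch.attach_hippocampus(cortex, LoopConfig(h=4, c=900, d=50))


def test_loop_delay_bounds():
    disp = LoopConfig(h=100, c=300, d=None, dispersion=True)
    assert disp.loop_delay_bounds() == (12, 100)
    uni = LoopConfig(h=100, c=300, d=50)
    assert uni.loop_delay_bounds() == (101, 101)


def test_config_validation():
    with pytest.raises(ConfigurationError):
        LoopConfig(h=-1, c=300, d=50)
    with pytest.raises(ConfigurationError):
        LoopConfig(h=10, c=0, d=50)
    with pytest.raises(ConfigurationError):
        LoopConfig(h=10, c=300, d=50, dispersion=True)
    with pytest.raises(ConfigurationError):
        LoopConfig(h=10, c=300, d=None, dispersion=False)


# -- noise -------------------------------------------------------------------


def test_thalamic_noise_schedule():
    sched = thalamic_noise(100.0, 1000, seed=0)
    assert len(sched) == 100
    assert (sched.amp == 20.0).all()
    assert (sched.neuron < N_CTX).all()
    assert len(thalamic_noise(0.0, 1000, seed=0)) == 0
    assert len(thalamic_noise(1000.0, 1000, seed=0)) == 1000


def test_quiet_network_stays_silent():
    net = build_cortex(seed=1)
    raster = net.run(500, seed=0, noise_rate_hz=0.0)
    assert len(raster) == 0


# -- spike propagation -------------------------------------------------------


def test_delay_buffer_single_synapse(micro_net_factory):
    """A spike crosses its one synapse exactly once, after its delay."""
    net = micro_net_factory(2, [(0, 1, 30.0, 7, False, np.inf)])
    stim = StimulusSchedule(np.array([10]), np.array([0]), np.array([100.0]))
    raster = net.run(60, stimuli=stim, seed=0)
    t0 = raster.times[raster.neurons == 0]
    t1 = raster.times[raster.neurons == 1]
    assert len(t0) == 1 and len(t1) == 1
    lag = t1[0] - t0[0]
    assert 7 <= lag <= 12  # delay plus spike-initiation latency


def test_engine_matches_naive_event_queue_oracle(micro_net_factory):
    """The vectorised engine reproduces a straightforward per-neuron
    reference simulation (dict-based delivery queue) spike for spike."""
    rng = np.random.default_rng(0)
    n = 5
    synapses = []
    for pre in range(n):
        for post in range(n):
            if pre != post and rng.random() < 0.6:
                synapses.append((pre, post, rng.uniform(2, 12), int(rng.integers(1, 9)),
                                 False, np.inf))
    stim_t = np.sort(rng.integers(5, 150, size=12))
    stim_n = rng.integers(0, n, size=12)
    stim_a = rng.uniform(15, 25, size=12)

    net = micro_net_factory(n, synapses)
    raster = net.run(200, stimuli=StimulusSchedule(stim_t, stim_n, stim_a), seed=0)

    # independent reference: plain python, same update equations
    v = [-70.0] * n
    u = [-14.0] * n
    pending: dict[int, list[float]] = {}
    ref = []
    for t in range(200):
        I = [0.0] * n
        for nid in pending.pop(t, []):
            I[int(nid[0])] += nid[1]
        for tt, nn, aa in zip(stim_t, stim_n, stim_a):
            if tt == t:
                I[int(nn)] += aa
        fired = [False] * n
        for _half in range(2):
            for i in range(n):
                if fired[i]:
                    continue
                v[i] += 0.5 * (0.04 * v[i] * v[i] + 5 * v[i] + 140 - u[i] + I[i])
                u[i] += 0.5 * (0.02 * (0.2 * v[i] - u[i]))
                if v[i] >= 30.0:
                    fired[i] = True
        for i in range(n):
            if fired[i]:
                ref.append((t, i))
                v[i] = -65.0
                u[i] += 8.0
                for (pre, post, w, d, _pl, _cap) in synapses:
                    if pre == i:
                        pending.setdefault(t + d, []).append((post, w))
    got = sorted(zip(raster.times.astype(int), raster.neurons.astype(int)))
    assert got == sorted(ref)


def test_seeded_runs_are_identical(adjusted_net):
    rng = np.random.default_rng(9)
    stim = ch.present(ch.PATTERN_A, 100, np.random.default_rng(1))
    r1 = adjusted_net.copy().run(400, stimuli=stim, seed=5)
    r2 = adjusted_net.copy().run(400, stimuli=stim, seed=5)
    assert (r1.times == r2.times).all() and (r1.neurons == r2.neurons).all()
    assert len(r1) > 0


def test_relay_fidelity(adjusted_net):
    """Every hippocampal input spike is echoed by its paired output neuron
    shortly after the relay delay."""
    net = adjusted_net.copy()
    rng = np.random.default_rng(4)
    raster = net.run(500, stimuli=ch.present(ch.PATTERN_A, 300, rng), seed=6,
                     plasticity=False)
    hin = raster.select("hipp_in")
    hout = raster.select("hipp_out")
    assert len(hin) > 0
    h = adjusted_net.cfg.h
    for t, nid in zip(hin.times, hin.neurons):
        mate = hout.times[hout.neurons == nid + h]
        assert ((mate >= t + 1) & (mate <= t + 8)).any()
    assert len(hout) == len(hin)


def test_lesion_is_reversible(adjusted_net):
    net = adjusted_net.copy()
    fwd = net.syn.cls == CLS_CTX_HIPP
    before = net.syn.weight[fwd].copy()
    net.lesion_hippocampus()
    assert (net.syn.weight[fwd] == 0.0).all()
    assert not net.plasticity.enabled
    rng = np.random.default_rng(4)
    raster = net.run(500, stimuli=ch.present(ch.PATTERN_A, 300, rng), seed=6)
    assert len(raster.select("hipp_in")) == 0
    net.unlesion_hippocampus()
    assert (net.syn.weight[fwd] == before).all()
    assert net.plasticity.enabled


def test_overload_is_flagged_not_raised(micro_net_factory):
    """Sustained near-total firing sets the overload flag on the result."""
    n = 20
    synapses = [
        (i, j, 30.0, 1, False, np.inf) for i in range(n) for j in range(n) if i != j
    ]
    net = micro_net_factory(n, synapses)
    stim = StimulusSchedule(
        np.zeros(n, dtype=np.int64), np.arange(n), np.full(n, 100.0)
    )
    raster = net.run(700, stimuli=stim, seed=0)
    assert raster.overload
    assert net.overload


def test_raster_partitions_and_selection(adjusted_net):
    parts = adjusted_net.partitions
    assert parts["ctx_exc"] == (0, 800)
    assert parts["hipp_out"] == (1100, 1200)
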