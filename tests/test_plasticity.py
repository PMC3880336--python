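import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cortohipp as ch
from cortohipp.circuit import CLS_CTX_EXC, CLS_CTX_HIPP, CLS_HIPP_CTX, StimulusSchedule
from cortohipp.plasticity import (
    PlasticityParams,
    apply_plasticity,
    stdp_delta,
    stdp_delta_weight_dependent,
)

P = PlasticityParams()


def test_delta_at_zero_lag_is_full_potentiation():
    assert stdp_delta(10.0, 5.0, 15.0, P) == pytest.approx(P.A_plus)


def test_delta_decays_to_zero_at_large_lags():
    assert stdp_delta(0.0, 1.0, 1e5, P) == pytest.approx(0.0, abs=1e-12)
    assert stdp_delta(1e5, 1.0, 0.0, P) == pytest.approx(0.0, abs=1e-12)


def test_delta_closed_form_example():
    # pre at 10 ms, delay 5 ms, post at 20 ms -> lag 5 ms
    assert stdp_delta(10.0, 5.0, 20.0, P) == pytest.approx(0.1 * math.exp(-5 / 20))


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    pre=st.floats(0, 500),
    delay=st.floats(1, 90),
    post=st.floats(0, 500),
)
def test_delta_sign_matches_lag(pre, delay, post):
    lag = post - (pre + delay)
    d = stdp_delta(pre, delay, post, P)
    if lag >= 0:
        assert d > 0
    else:
        assert d < 0
    assert abs(d) <= max(P.A_plus, P.A_minus)


@pytest.mark.parametrize(
    "weight, sign, expected_scale",
    [(5.0, +1, 0.0), (0.0, -1, 0.0), (2.5, +1, 0.5), (2.5, -1, 0.5)],
)
def test_weight_dependent_boundary_scaling(weight, sign, expected_scale):
    cap = 5.0
    if sign > 0:
        base = stdp_delta(0.0, 1.0, 2.0, P)  # potentiating pairing
        d = stdp_delta_weight_dependent(0.0, 1.0, 2.0, weight, cap, P)
    else:
        base = stdp_delta(0.0, 1.0, 0.0 - 2.0, P)  # depressing pairing
        d = stdp_delta_weight_dependent(0.0, 1.0, 0.0 - 2.0, weight, cap, P)
    assert d == pytest.approx(base * expected_scale)


def test_params_validation():
    with pytest.raises(ValueError):
        PlasticityParams(rule="triphasic")
    with pytest.raises(ValueError):
        PlasticityParams(A_plus=-0.1)
    with pytest.raises(ValueError):
        PlasticityParams(tau_plus=0.0)


def test_engine_accumulation_matches_offline_rule(micro_net_factory):
    """One forced pre/post pairing: the online trace-based accumulation and
    the offline closed-form application agree on the weight change."""
    pp = PlasticityParams(accumulator_retention=0.0)
    delay = 10
    w0 = 1.0
    net = micro_net_factory(2, [(0, 1, w0, delay, True, 10.0)], plasticity=pp)
    stim = StimulusSchedule(
        np.array([100, 118]), np.array([0, 1]), np.array([100.0, 100.0])
    )
    raster = net.run(1000, stimuli=stim, seed=0)
    engine_dw = net.syn.weight[0] - w0

    offline = micro_net_factory(2, [(0, 1, w0, delay, True, 10.0)], plasticity=pp)
    apply_plasticity(offline, raster, pp)
    offline_dw = offline.syn.weight[0] - w0
    assert engine_dw == pytest.approx(offline_dw, abs=1e-9)
    # and both equal the scalar rule for the recorded spike times
    t_pre = raster.times[raster.neurons == 0][0]
    t_post = raster.times[raster.neurons == 1][0]
    assert engine_dw == pytest.approx(stdp_delta(t_pre, delay, t_post, pp))


def test_weights_clamped_to_class_bounds(trained_d50):
    syn = trained_d50.syn
    ctx = syn.cls == CLS_CTX_EXC
    assert syn.weight[ctx].min() >= 0.0 and syn.weight[ctx].max() <= 10.0
    back = syn.cls == CLS_HIPP_CTX
    assert syn.weight[back].min() >= 0.0 and syn.weight[back].max() <= 5.0


def test_forward_projections_untouched_by_training(trained_d50):
    """ctx->hipp weights are predefined and not modified by STDP."""
    fresh = ch.make_network(ch.LoopConfig(h=100, c=300, d=50), seed=3)
    fwd_t = trained_d50.syn.cls == CLS_CTX_HIPP
    fwd_f = fresh.syn.cls == CLS_CTX_HIPP
    assert np.array_equal(trained_d50.syn.weight[fwd_t], fresh.syn.weight[fwd_f])


def test_training_potentiates_target_backprojections(trained_d50):
    syn = trained_d50.syn
    back = syn.cls == CLS_HIPP_CTX
    onto_B = back & np.isin(syn.post, np.asarray(ch.PATTERN_B.ids))
    elsewhere = back & ~np.isin(syn.post, np.asarray(ch.PATTERN_B.ids))
    assert syn.weight[onto_B].mean() > 10 * syn.weight[elsewhere].mean()


def test_pairing_compression_shortens_the_interval(micro_net_factory):
    """Training a 10 ms-delay synapse with an 18 ms pre/post interval grows
    the weight until the presynaptic spike alone drives the target, which
    then fires at the synaptic delay instead of the trained interval."""
    delay = 10
    net = micro_net_factory(2, [(0, 1, 1.0, delay, True, 25.0)])
    for k in range(40):
        stim = StimulusSchedule(np.array([300, 318]), np.array([0, 1]),
                                np.array([100.0, 100.0]))
        net.run(1300, stimuli=stim, seed=k, plasticity=True)
    assert net.syn.weight[0] > 15.0
    recall = net.copy()
    stim = StimulusSchedule(np.array([300]), np.array([0]), np.array([100.0]))
    raster = recall.run(400, stimuli=stim, seed=99, plasticity=False)
    t0 = raster.times[raster.neurons == 0][0]
    t1 = raster.times[raster.neurons == 1]
    assert t1.size == 1
    interval = t1[0] - t0
    assert interval < 18.0
    assert delay <= interval <= delay + 5


def test_chain_compression_latency_decreases(micro_net_factory):
    """Ten neurons firing a 5 ms-spaced sequence converge on one target;
    initially only the last two make it fire, but with repeated training the
    target's latency (relative to sequence onset) shrinks."""
    n = 11  # neurons 0..9 in sequence, 10 is the target
    synapses = [(i, 10, 15.0 if i >= 8 else 1.0, 1, True, 20.0) for i in range(10)]
    net = micro_net_factory(n, synapses)

    def latency(net):
        probe = net.copy()
        times = 300 + 5 * np.arange(10)
        stim = StimulusSchedule(times, np.arange(10), np.full(10, 100.0))
        r = probe.run(450, stimuli=stim, seed=1, plasticity=False)
        tk = r.times[r.neurons == 10]
        return tk[0] - 300 if tk.size else np.inf

    lat0 = latency(net)
    lats = [lat0]
    for epoch in range(30):
        times = 300 + 5 * np.arange(10)
        stim = StimulusSchedule(times, np.arange(10), np.full(10, 100.0))
        net.run(1300, stimuli=stim, seed=100 + epoch, plasticity=True)
        lats.append(latency(net))
    assert lats[-1] < lat0
    # monotone non-increasing up to a small numerical tolerance
    assert all(b <= a + 0.5 for a, b in zip(lats, lats[1:]))
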