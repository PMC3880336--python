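"""Raster-derived statistics.

Covers the oscillation detector used to label network behaviour, the
extraction and comparison of hippocampal spatio-temporal signatures, and
the decomposition of recalled target spikes into their driving mechanisms.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from . import circuit as _c
from .dynamics import EXCITATORY, min_current_to_spike

# -- oscillation detection ---------------------------------------------------

JUMP_THRESHOLD_SPIKES = 150
FREQ_BAND_HZ = (4.0, 40.0)
DOMINANCE_RATIO = 5.0


@dataclass(frozen=True)
class OscillationVerdict:
    flagged: bool
    max_bin_jump: float
    dominant_freq: float
    dominance_ratio: float


def detect_oscillation(
    raster: _c.SpikeRaster,
    window_ms: float = 1000.0,
    bin_ms: float = 10.0,
) -> OscillationVerdict:
    """Strong-oscillation test on the trailing ``window_ms`` of a raster.

    Spiking neurons are counted in ``bin_ms`` intervals; the network is
    flagged when some adjacent-bin increase exceeds 150 spikes AND the
    spectrum of the binned histogram has its largest 4-40 Hz coefficient at
    least five times the mean of all (non-DC) coefficients.  Pure function
    of the raster.
    """
    if len(raster) == 0:
        return OscillationVerdict(False, 0.0, 0.0, 0.0)
    t1 = float(raster.times.max()) + 1.0
    t0 = max(0.0, t1 - window_ms)
    m = raster.times >= t0
    times, neurons = raster.times[m], raster.neurons[m]
    n_bins = int(round(window_ms / bin_ms))
    b = np.minimum(((times - t0) / bin_ms).astype(np.int64), n_bins - 1)
    # distinct neurons per bin
    uniq = np.unique(b * (neurons.max() + 1) + neurons)
    counts = np.bincount(uniq // (neurons.max() + 1), minlength=n_bins).astype(float)
    jump = float(np.max(np.diff(counts))) if n_bins > 1 else 0.0
    mags = np.abs(np.fft.rfft(counts))
    freqs = np.fft.rfftfreq(n_bins, d=bin_ms / 1000.0)
    band = (freqs >= FREQ_BAND_HZ[0]) & (freqs <= FREQ_BAND_HZ[1])
    mean_mag = float(mags[1:].mean()) if mags.shape[0] > 1 else 0.0
    if band.any() and mean_mag > 0:
        k = np.argmax(np.where(band, mags, -np.inf))
        dominant = float(freqs[k])
        ratio = float(mags[k] / mean_mag)
    else:
        dominant, ratio = 0.0, 0.0
    flagged = (jump > JUMP_THRESHOLD_SPIKES) and (ratio >= DOMINANCE_RATIO)
    return OscillationVerdict(flagged, jump, dominant, ratio)


# -- hippocampal signatures --------------------------------------------------


@dataclass
class Signature:
    """Hippocampal output spikes evoked by one cortical pattern, as times
    relative to stimulus onset within an observation window."""

    neurons: np.ndarray
    times: np.ndarray
    window_ms: float

    def __len__(self):
        return self.neurons.shape[0]

    def by_neuron(self) -> dict[int, np.ndarray]:
        out: dict[int, np.ndarray] = {}
        for n in np.unique(self.neurons):
            out[int(n)] = np.sort(self.times[self.neurons == n])
        return out


def default_signature_window(cfg: _c.LoopConfig) -> float:
    """Observation window covering the full loop-latency range."""
    if cfg.dispersion:
        return 120.0
    return 2.0 * cfg.d + 20.0


def extract_signatures(
    network: _c.Network,
    patterns,
    seed: int = 0,
    window_ms: float | None = None,
    spacing_ms: int = 400,
) -> list[Signature]:
    """Signatures of several patterns from one plasticity-frozen run.

    Presentations are spaced ``spacing_ms`` apart, long enough for the loop
    to clear between patterns; the network copy is discarded afterwards, so
    the caller's network is untouched.
    """
    from .protocols import present  # local import to avoid a cycle

    if network.h == 0:
        raise ValueError("network has no hippocampal loop")
    if window_ms is None:
        window_ms = default_signature_window(network.cfg)
    if spacing_ms < window_ms:
        raise ValueError("spacing_ms must cover the observation window")
    rng = np.random.default_rng(seed)
    net = network.copy()
    onsets = 300 + np.arange(len(patterns)) * spacing_ms
    stims = [present(p, int(t), rng) for p, t in zip(patterns, onsets)]
    raster = net.run(
        int(onsets[-1] + spacing_ms),
        stimuli=_c.StimulusSchedule.merge(*stims),
        seed=int(rng.integers(2**31)),
        plasticity=False,
    ).select("hipp_out")
    out = []
    for t0 in onsets:
        w = raster.window(t0, t0 + window_ms)
        out.append(Signature(w.neurons.copy(), w.times - t0, float(window_ms)))
    return out


def extract_signature(
    network: _c.Network,
    pattern,
    seed: int = 0,
    window_ms: float | None = None,
) -> Signature:
    """Signature of a single pattern (see :func:`extract_signatures`)."""
    return extract_signatures(network, [pattern], seed=seed, window_ms=window_ms)[0]


def signature_overlap(s1: Signature, s2: Signature, tolerance_ms: float = 2.0) -> float:
    """Percentage of spikes matched between two signatures.

    A spike of ``s1`` matches when the same neuron spikes in ``s2`` within
    the tolerance; each spike is matched at most once, greedily in time
    order.  Normalised by the larger signature so the measure is symmetric;
    two empty signatures overlap 0 %.
    """
    n1, n2 = len(s1), len(s2)
    if n1 == 0 or n2 == 0:
        return 0.0
    g1, g2 = s1.by_neuron(), s2.by_neuron()
    matched = 0
    for neuron, t1 in g1.items():
        t2 = g2.get(neuron)
        if t2 is None:
            continue
        i = j = 0
        while i < len(t1) and j < len(t2):
            dt = t1[i] - t2[j]
            if abs(dt) <= tolerance_ms:
                matched += 1
                i += 1
                j += 1
            elif dt > 0:
                j += 1
            else:
                i += 1
    return 100.0 * matched / max(n1, n2)


def max_pairwise_overlap(signatures, tolerance_ms: float = 2.0) -> float:
    """Largest overlap over all unordered pairs of signatures."""
    best = 0.0
    for i in range(len(signatures)):
        for j in range(i + 1, len(signatures)):
            best = max(best, signature_overlap(signatures[i], signatures[j], tolerance_ms))
    return best


# -- drive decomposition -----------------------------------------------------

DIRECT_SINGLE_SOURCE = "direct_single_source"
TIMED_MULTI_SOURCE = "timed_multi_source"
RECURRENT_CORTICAL = "recurrent_cortical"


@lru_cache(maxsize=1)
def _single_input_threshold() -> float:
    return min_current_to_spike(EXCITATORY)


def decompose_target_drive(
    network: _c.Network,
    raster: _c.SpikeRaster,
    target_ids,
    window_ms: float = 10.0,
    threshold_mv: float | None = None,
) -> dict[int, str]:
    """Classify how each spiking target neuron was driven during recall.

    For the neuron's first spike, hippocampal output spikes arriving through
    the backprojections within ``window_ms`` beforehand are collected:

    - ``direct_single_source``: one presynaptic hippocampal neuron's
      simultaneously arriving weight alone reaches the single-pulse firing
      threshold of a rested neuron;
    - ``timed_multi_source``: only the combined timed hippocampal input does;
    - ``recurrent_cortical``: hippocampal input cannot account for the
      spike, which must come from recurrent cortical connections.

    The classes partition the spiking target neurons.
    """
    if threshold_mv is None:
        threshold_mv = _single_input_threshold()
    syn = network.syn
    if network.h:
        hipp = raster.select("hipp_out")
        spikes_of = {
            int(p): hipp.times[hipp.neurons == p] for p in np.unique(hipp.neurons)
        }
    else:
        spikes_of = {}
    back = np.flatnonzero(syn.cls == _c.CLS_HIPP_CTX)
    by_target: dict[int, np.ndarray] = {}
    for n in np.unique(syn.post[back]):
        by_target[int(n)] = back[syn.post[back] == n]
    out: dict[int, str] = {}
    target_ids = np.asarray(target_ids)
    for nid in target_ids:
        t_spk = raster.times[(raster.neurons == nid)]
        if t_spk.size == 0:
            continue
        ts = float(t_spk.min())
        arr_pre, arr_t, arr_w = [], [], []
        for s in by_target.get(int(nid), ()):
            pre_times = spikes_of.get(int(syn.pre[s]))
            if pre_times is None:
                continue
            at = pre_times + syn.delay[s]
            sel = (at > ts - window_ms) & (at <= ts)
            for a in at[sel]:
                arr_pre.append(int(syn.pre[s]))
                arr_t.append(float(a))
                arr_w.append(float(syn.weight[s]))
        if not arr_w:
            out[int(nid)] = RECURRENT_CORTICAL
            continue
        arr_pre = np.array(arr_pre)
        arr_t = np.array(arr_t)
        arr_w = np.array(arr_w)
        single_max = 0.0
        for p in np.unique(arr_pre):
            for t0 in np.unique(arr_t[arr_pre == p]):
                single_max = max(
                    single_max, arr_w[(arr_pre == p) & (arr_t == t0)].sum()
                )
        if single_max >= threshold_mv:
            out[int(nid)] = DIRECT_SINGLE_SOURCE
        elif arr_w.sum() >= threshold_mv:
            out[int(nid)] = TIMED_MULTI_SOURCE
        else:
            out[int(nid)] = RECURRENT_CORTICAL
    return out
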