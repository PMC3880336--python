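# Methods

## Model

### Neurons and integration

All neurons are two-variable quadratic (Izhikevich-type) point neurons,

    dv/dt = 0.04 v^2 + 5 v + 140 − u + I
    du/dt = a (b v − u)

with after-spike reset `v ← r1`, `u ← u + r2` at the 30 mV threshold.
Excitatory neurons (cortical and hippocampal) use the regular-spiking
preset (a=0.02, b=0.2, r1=−65, r2=8); inhibitory cortical neurons the
fast-spiking preset (a=0.1, b=0.2, r1=−65, r2=2). Integration is forward
Euler with a 0.5 ms step; inputs are delivered on a 1 ms grid and held
constant over both half-steps of the delivery millisecond, matching the
reference integration scheme for this model family. Neurons that cross
threshold mid-tick are clamped to 30 mV (bounding recorded waveforms) and
reset at the end of the tick.

Two consequences of this scheme matter throughout:

- The regular-spiking preset's stable equilibrium is (v, u) = (−70, −14),
  not the reset point (−65, −13). "Rest" in this package always means the
  equilibrium; an unstimulated neuron relaxes there within ~100 ms.
- From rest, the minimal 1 ms current pulse that elicits a spike is
  ≈ 16.5–18 mV (bisection, `min_current_to_spike`). A single 20 mV pulse
  fires at ≈ 4 ms; pulses just above threshold fire after a slow crawl of
  up to ~10 ms. With backprojection weights capped at 5 mV this puts the
  minimum number of simultaneous maximal hippocampal inputs needed to fire
  a cortical neuron at exactly 4.

### Circuit

The cortex has 800 excitatory and 200 inhibitory neurons, 100 outgoing
synapses per neuron to distinct random cortical targets, inhibitory →
excitatory only. Excitatory delays are integer-uniform 1–20 ms, inhibitory
delays 1 ms, inhibitory weights fixed at −5 mV.

The hippocampal loop adds `h` input and `h` output neurons. Forward
projections: `c` fixed synapses per input neuron from random excitatory
cortical neurons. Relay: one fixed 30 mV synapse input_i → output_i
(exempt from clamps and plasticity; guarantees the one-to-one
input/output correspondence). Backprojections: `c` plastic synapses per
output neuron onto random excitatory cortical neurons, clamped to
[0, 5] mV. Delay layouts:

- uniform: `d` ms forward and backward, 1 ms relay (total loop 2d+1 —
  treating the relay as a pure grid-minimum hop keeps the d=50 loop at
  ~100 ms, which is what places the loop-mediated association range at
  110–150 ms);
- dispersion: forward/backward integer-uniform 1–5 ms, relay 10–90 ms, so
  the total loop spans exactly 12–100 ms.

Thalamic noise delivers 20 mV to one uniformly chosen **cortical** neuron
every 1000/rate ms (100 Hz in the adjusted model, 1000 Hz in the
unadjusted reference settings). Hippocampal neurons receive no external
input of any kind; only cortex can be stimulated.

### Plasticity

Additive STDP with the conduction delay inside the pairing:
`lag = t_post − (t_pre + delay)`; `Δw = +A+·exp(−lag/τ+)` for `lag ≥ 0`,
`−A−·exp(lag/τ−)` otherwise. Defaults A+ = 0.1, A− = 0.12,
τ+ = τ− = 20 ms, nearest-spike pairing via exponential traces. Deltas are
accumulated per synapse and applied once per simulated second with
clamping; the accumulator retains a factor 0.9 after each application (the
reference bookkeeping), which geometrically re-applies each pairing and
makes the *effective* per-pairing amplitude A/(1−0.9) = 10×A. This
effective rate is what quantitatively produces the observed association
cutoffs (see Calibration). The per-second +0.01 additive increment of the
reference scheme is exposed (`rate_increment`) but removed in the adjusted
model: under external drive it runs the network away. A weight-dependent
variant scales potentiation by (cap−w)/cap and depression by w/cap.

Plastic classes: excitatory-cortical → cortical (cap 10 mV) and
hippocampal-output → excitatory-cortical (cap 5 mV). Forward projections
and the relay are never modified.

## Calibration of parameters of no interest

The experiments require two basic properties: (i) synchronized activation
of a 50-neuron assembly must not trigger a reaction chain or loop
oscillation, and (ii) a pattern must recruit a calibrated 30–50 of the 100
hippocampal input neurons. Several parameters that the source conditions
leave open were fixed, once, by those two requirements:

- **Initial cortical excitatory weight = 1 mV.** With the slow
  subthreshold leak of the quadratic neuron, baseline weights ≳ 4 mV make
  three convergent inputs within ~5 ms common enough that any synchronized
  volley recruits a several-hundred-spike avalanche; the avalanche floods
  the hippocampus, re-ignites through the backprojections, and STDP then
  potentiates unspecifically. At 1 mV a volley evokes almost no secondary
  spikes while trained pathways still grow to the 10 mV cap.
- **Initial backprojection weight = 0.1 mV.** The untrained return volley
  (30–50 output neurons × ~0.375 convergence) must stay far below the
  ~17 mV ignition threshold under any recruitment; at ≥ 0.5 mV the loop
  can bootstrap a self-sustaining ~10 Hz oscillation through its own
  potentiation.
- **Forward weight mean = 0.9 mV (uniform variant), drawn uniform
  ±0.5 mV.** Chosen so a synchronized volley recruits 30–50 input neurons
  (≈ 37 on average). The instrumental value depends on the integrator's
  effective threshold; the recruitment band is the stated requirement.
- **Forward weight mean = 1.35 mV (dispersion variant).** The 1–5 ms
  forward delays spread the volley, so matching recruitment needs slightly
  stronger forward synapses. This value also keeps dispersed recall
  timing-coded: at ≥ 1.4 mV the dispersed return stream becomes strong
  enough to drive targets by temporal summation alone, erasing the
  spike-timing code that disambiguates stored pairs.

With the effective STDP amplitude of ~1 mV per near-coincident pairing,
the association cutoffs follow directly: direct cortical association
saturates A→B weights for separations up to ≈ 60 ms
(60 trials × exp(−lag/20 ms) × 1 mV reaches the cap) and fails beyond;
the d=50 loop delivers the cue's return ~105 ms after the cue, so targets
110–150 ms away are bridged while ~70–110 ms separations fall in the gap;
dispersion covers the gap with its 12–100 ms return stream.

## Experiment procedures

Patterns are 50-neuron excitatory assemblies (A, B, C, D are neuron blocks
0–49 … 150–199); presentation injects independent Normal(20, 1) mV for
1 ms. Training presents cue and target 60 times at separation Δt
(optionally jittered per trial) with 1000 ms of noise-only time between
trials — long enough for delay buffers, traces and membrane state to
clear. Retrieval quality is the number of distinct target neurons spiking
within 150 ms of cue onset, averaged over 10 cue-only trials; retrieval
latency is the mean over trials of the per-trial median target spike time
within 200 ms of the cue. Association "success" in sweep summaries means
quality ≥ 25 (half the assembly); the threshold is only used for binary
summaries and is configurable.

Consolidation runs cued recalls with plasticity on (noise stays on);
probes interleaved at chosen points measure latency and lesioned quality
on *copies* of the network, so probing never perturbs consolidation.
Lesioning zeroes the cortex→hippocampus forward weights and disables STDP,
reversibly.

The parameter-space sweep samples (h, c, d) networks, runs each for a few
simulated seconds with a single pattern kick, and labels strong
oscillation with the standard detector: distinct spiking neurons per 10 ms
bin over 1 s; flagged when some adjacent-bin increase exceeds 150 spikes
AND the binned histogram's largest 4–40 Hz Fourier coefficient is at least
five times the mean non-DC coefficient.

Signature analysis presents patterns to a plasticity-frozen copy and
collects hippocampal output spike times relative to onset (window 2d+20 ms
uniform, 120 ms dispersion). Overlap between two signatures counts spikes
of the same neuron matched greedily within ±2 ms, each spike at most once,
normalised by the larger signature (symmetric and conservative; greedy
matching is optimal for sorted one-dimensional intervals and is verified
against exhaustive matching in the tests).

## Problem sizes

Desk-scale sizes used by the test suite and the acceptance script, chosen
as the package's own defaults: 20 presentations for the recruitment
calibration; 100 random patterns for signature uniqueness; 10 independent
repetitions for the post-training latency of the uniform network; one
300-recall consolidation run; association-range claims asserted at
representative separations (40 and 120 ms for the cortex-only network, 90
and 120 ms for the d=50 loop, 90 ms for dispersion) rather than a full
5 ms grid; the parameter-space sweep defaults to tens of networks × a few
simulated seconds.

## Known limitations

- **Late-training unspecific recruitment (uniform variant).** Once the
  d=50 network recalls its target during training, the synchronized
  pre-volley plus noise-coincident pairings slowly recruit non-target
  neurons into the return response; after ~45–60 trials foil activity
  rises, and a second 60-trial training phase saturates it. The two-pair
  disambiguation experiment is therefore run in the dispersion variant,
  where the dispersed return keeps learning specific. Single-phase
  experiments in the uniform variant are unaffected.
- **Compression endpoint.** Repeated recall compresses dispersion
  retrieval from the trained ~85 ms to a plateau of ~16 ms rather than
  ~10 ms: the direct cortical path stacks two spike-initiation latencies
  (~4 ms for the cue assembly, ~3–6 ms for near-threshold target ignition)
  on top of the favoured 3–12 ms synaptic delays. The compression dynamics
  (monotone latency decrease, cortical transfer, lesion robustness) are
  reproduced; the absolute endpoint is a few ms high.
- The synthetic stimulation protocol drives every assembly member with a
  near-identical current, producing tighter volleys than natural input
  would; quantities that depend on volley synchrony (recruitment counts,
  signature sizes) are calibrated under that assumption and would shift
  under jittered stimulation.
- The model omits NMDA-style slow currents, hippocampal subfield
  structure, short-term plasticity and homeostatic scaling; stability is
  obtained by the manual calibration above, not by self-organisation.
  Sequences longer than two patterns and reverse replay are out of scope.
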