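# cortohipp

A spiking-network simulator for studying how the anatomy of the
cortico-hippocampal loop — convergent/divergent connectivity and
heterogeneous conduction delays — lets a small hippocampal population
address cortical cell assemblies, associate them across temporal gaps that
exceed the STDP window, and gradually consolidate those associations into
cortex through repeated recall.

It is aimed at computational neuroscientists who want a compact, fully
seeded model of systems consolidation: every experiment (association
training, cued recall, consolidation by recall, lesion tests, parameter
sweeps) is a library call or a CLI subcommand, and every run is exactly
reproducible from its seeds.

## The model

**Cortex.** 1000 Izhikevich point neurons (800 regular-spiking excitatory,
200 fast-spiking inhibitory), each with 100 outgoing synapses to distinct
random cortical targets; inhibitory neurons contact excitatory neurons
only. Membrane dynamics

```
dv/dt = 0.04 v^2 + 5 v + 140 - u + I
du/dt = a (b v - u),          v >= 30 mV  =>  v <- r1,  u <- u + r2
```

integrated by forward Euler with a 0.5 ms step on a 1 ms event grid.
Excitatory conduction delays are integer-uniform in 1–20 ms. A stimulus is
a 50-neuron assembly whose members each receive an independent
Normal(20, 1) mV current for 1 ms; thalamic background noise delivers
20 mV to one random cortical neuron every 10 ms (100 Hz).

**Hippocampal loop.** `h` input neurons each receive `c` fixed forward
synapses from random excitatory cortical neurons; a strong one-to-one relay
drives `h` output neurons; each output neuron sends `c` plastic
backprojections (clamped to [0, 5] mV) to random excitatory cortical
neurons. Delays are either uniform (`d` each way) or dispersed
(cortex↔hippocampus 1–5 ms, relay 10–90 ms), so a synchronous cortical
volley returns as a spike stream spread over 12–100 ms.

**Plasticity.** Additive STDP with conduction delays included in the
pairing (`lag = t_post − t_pre − delay`), A+ = 0.1, A− = 0.12, τ = 20 ms,
nearest-spike pairing, deltas accumulated and applied once per simulated
second. A weight-dependent variant is available. Plastic classes: all
excitatory cortical synapses and the hippocampo-cortical backprojections.

## A worked example

```python
import cortohipp as ch

# the adjusted reference network: h=100, c=300, uniform 50 ms delays
net = ch.make_network(ch.LoopConfig(h=100, c=300, d=50), seed=3)

# store A -> B with a 120 ms separation, far beyond the cortical STDP range
sched = ch.TrainingSchedule(ch.PATTERN_A, ch.PATTERN_B, delta_t=120.0, trials=60)
ch.train_association(net, sched, seed=11)

res = ch.recall(net, ch.PATTERN_A, ch.PATTERN_B, n_trials=10, seed=12)
print(f"target quality {res.retrieval_quality:.1f}/50, "
      f"foil {res.quality_for(ch.PATTERN_D):.1f}/50, "
      f"median latency {res.median_latency:.1f} ms")
```

prints

```
target quality 49.7/50, foil 0.8/50, median latency 114.0 ms
```

Cueing pattern A alone retrieves essentially the whole target assembly B
(49.7 of 50 neurons within the 150 ms scoring window) while an untrained
foil assembly D stays at the noise floor; the ~114 ms latency is the round
trip through the 50 ms loop — the association is held by the hippocampal
backprojections, not by direct cortical synapses. Lesioning the loop
(`net.lesion_hippocampus()`) abolishes recall right after training, and
repeated plasticity-on recalls (`ch.consolidate`) progressively transfer
the association to cortex until it survives the lesion.

The same experiments are available from the shell:

```
cortohipp train --config examples/uniform.yaml --seed 1 --out runs/train
cortohipp consolidate --config examples/dispersion.yaml --seed 1 --out runs/cons
cortohipp sweep-range --config examples/uniform.yaml --variant dispersion \
    --grid 10,40,70,100,130 --seed 1 --out runs/sweep
```

Each subcommand writes delimited result tables, spike rasters
(`time_ms<TAB>neuron_id`) and a `manifest.json` echoing the configuration
and the full seed tree.

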