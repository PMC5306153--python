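# spinemk

A headless Python toolkit for **layered declarative neural models**: point
spiking neurons and rate-coded units described in three separable XML
layers — *components* (the dynamical equations), *networks* (populations
and their projections) and *experiments* (stimuli, recordings, property
overrides) — plus a procedural 3D layout engine, pluggable script-based
connectivity generation, and a fixed-step reference simulator.

It is aimed at computational neuroscientists who want models that are
simulator-independent and machine-checkable: every model is a set of plain
XML files that validate against explicit structural rules, every source of
randomness flows from a named seed, and everything a graphical front-end
would do interactively (duplicate a component, copy property tables, lay
neurons out in 3D, generate distance-based connectivity) is a library call.

## The model stack

**Components** are hybrid dynamical systems: parameters, state variables,
aliases (derived quantities), typed ports (*analog* values, bare *event*
spikes, payload-carrying *impulses*) and regimes. Each regime holds
first-order differential equations `dx/dt = f(x, θ, inputs)` integrated by
forward Euler, and transitions fired on boolean conditions (false→true
edges), incoming events, or incoming impulses. Ports only connect when
kind and dimension (mV, pA, ms, …) both match.

**Networks** bind populations to components and wire them with projections;
each synapse pairs a connectivity scheme (one-to-one, all-to-all, fixed
probability, or an explicit `(source, destination, delay)` connection
list) with a weight-update and a postsynapse component. Connection lists
produced by generator scripts carry their *generation recipe* (script text,
parameter values, population sizes) in an annotations namespace, so the
file stays a plain, valid model for any reader while the list can be
regenerated — and is only regenerated when script, parameters or sizes
actually change.

**Experiments** hold duration and step size, analog/spike inputs, loggers
and property overrides, so one model can be probed under many paradigms
without touching the network files.

Shipped fixtures include a channel-wise basal-ganglia action-selection
network of leaky integrators (`τ ȧ = −a + u`, output clipped to [0, 1]),
its mechanical conversion into a spiking network of leaky
integrate-and-fire neurons (each unit widened to 7 neurons, weights ÷ 7,
current-valued parameters × 10 except the subthalamic intrinsic current,
membrane time constants ~ U(20, 30) ms, 4 ms exponential current synapses,
cortical drive as regular spike trains), and a striatal-like microcircuit
in a 300 µm cube with distance-based connectivity. Spike trains are turned
into rates by convolution with unit-area Gaussian kernels (σ = 100 ms), and
a basal-ganglia channel counts as *selected* while its output-nucleus
activity sits strictly below 0.1 (rate model) or 10 Hz (spiking model).

## Worked example

Build the six-channel selection network, drive channels 1–2 with step
inputs (channel 1: 0.4 from t = 1 s, 0.6 from t = 3 s; channel 2: 0.6 from
t = 2 s), and read out selection:

```python
import numpy as np
from spinemk import analysis, fixtures, simulator

project = fixtures.build_selection_network()          # 6-channel rate model
experiment = project.experiments[0]                   # step drive, ch 1-2
rt = simulator.build_runtime(project, experiment, master_seed=1)
logs = simulator.run(rt)

snr = logs.analog["snr_out"]                          # output nucleus
selected = snr.data < analysis.RATE_MODEL_THRESHOLD
for t_probe in (0.5, 2.5, 5.5):
    i = np.argmin(np.abs(snr.times - t_probe))
    print(f"t = {t_probe:.1f} s  SNr = {np.round(snr.data[i, :3], 3)}"
          f"  selected channels: {np.flatnonzero(selected[i]).tolist()}")
```

prints

```
t = 0.5 s  SNr = [0.214 0.214 0.214]  selected channels: []
t = 2.5 s  SNr = [0.014 0.    0.214]  selected channels: [0, 1]
t = 5.5 s  SNr = [0.    0.    0.214]  selected channels: [0, 1]
```

Before any input every channel shows the tonic output-nucleus activity
(0.214). Once cortical drive arrives, the driven channels' striatal D1
units inhibit their output-nucleus channels below the 0.1 threshold —
*disinhibition*, the selection signal — while the undriven channel keeps
its tonic hold. With both channels driven at equal strength the network
reports dual selection.

The same project converts to its spiking counterpart and round-trips
through files:

```python
snn = fixtures.convert_rate_to_snn(project, seed=1)   # 42 neurons/population
from spinemk.network import write_project, read_project
write_project(snn, "snn_project")                     # plain XML files
assert read_project("snn_project") == snn
```

A command-line front-end mirrors the library:

```sh
smk fixtures gpr --channels 6 --out gpr_project
smk validate-project gpr_project
smk run gpr_project --seed 1 --out results
smk convert-snn gpr_project --seed 1 --out snn_project
```

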