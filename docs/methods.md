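# Methods

This note records the modelling conventions, numerical choices and open
design decisions behind spinemk, in the spirit of a simulator's model
documentation. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Units and time

Time is milliseconds end to end inside the engine: the integration step
`dt` is in ms, time derivatives are "per ms", the builtin symbol `t`
(always in scope in component expressions) is in ms, and all shipped time
constants (25 ms leaky integrators, 20–30 ms membranes, 4 ms synapses,
2 ms refractory) are ms. Experiment durations and input time points are
seconds, converted once at the boundary; spike logs report seconds.
Coordinates are micrometres; delays are milliseconds.

The dimension system is label equality only — `mV`, `pA`, `nA`, `nS`,
`ms`, `s`, `Hz`, `dimensionless` — with no conversion arithmetic. Two
ports connect iff their kinds (analog/event/impulse) and labels both
match. This is deliberately a type check, not a unit algebra.

## Components

A component is a hybrid dynamical system: parameters, state variables,
aliases, typed ports, regimes. Conventions:

* **Expression grammar**: `+ - * /`, right-associative `^`, unary minus,
  parentheses, `exp log sin cos sqrt abs floor` (unary), `pow min max mod`
  (binary), comparisons and `&& || !` (booleans evaluate to 0/1).
  `floor` and `mod` exist so grid layouts can be written as ordinary
  layout equations. `rand()` is a layout-engine facility and is rejected
  inside components. Identifiers are case-sensitive.
* **Send-port value sources.** An analog send port exposes the state
  variable or alias with the same name; an impulse send port takes its
  payload from the same-named parameter, state variable or alias (so a
  weight-update's impulse port `w` carries its weight parameter). These
  are the only permitted name collisions; everything else shares one
  namespace per component.
* **Alias cycles** are rejected at validation; evaluation is topological.
* **Stateless components** (pure relays) are legal but flagged with a
  warning — the cortical relay and the rate postsynapse use this.

## Reference simulator

Fixed-step forward Euler only; `dt` comes from the experiment (fixtures
use 1 ms for the rate model, 0.1 ms for spiking runs, and 0.01 ms where a
fit demands it). Within a step:

1. analog send values are read from previous-step state everywhere
   (synchronous/Jacobi propagation between populations, so declaration
   order cannot matter);
2. values flow through each synapse's weight-update (one instance per
   connection) and postsynapse (one instance per target neuron — exact
   for current-summing synapses, and the reason reduce ports exist) and
   through generic inputs, summing on reduce ports;
3. experiment analog inputs are added (piecewise-constant hold, no
   interpolation; with an index subset the value is broadcast to the
   subset);
4. one Euler step for every group;
5. condition transitions fire on false→true edges only (a condition that
   is already true when a regime is entered must go false first), ties
   resolved in declaration order;
6. emissions are enqueued: connection delays are rounded to the nearest
   step with a minimum of one step on spike legs; the weight-update →
   postsynapse impulse hop inside a synapse is immediate because the
   connection delay was spent on the spike leg. Analog connections carry
   delay 0 only.
7. due events/impulses are delivered (FIFO within a step; simultaneous
   impulses onto one target accumulate via scatter-add when the
   assignment has the form `x = x + f(payload)`);
8. edge memories refresh and loggers sample.

Analog traces have `floor(duration/dt) + 1` rows (initial state plus one
per step). A non-finite state aborts with population, neuron, variable and
step named. Every random draw (property sampling, probabilistic
connectivity, layout streams) comes from NumPy's PCG64 generator seeded by
SHA-256 hashing of the master seed and the object's path, so identical
(project, experiment, master seed) gives bit-identical logs across
processes; the stream algorithm is pinned by this choice.

`ComponentBench` drives a single component in isolation with scripted
analog drives and event/impulse injections; the closed-form checks
(charging curve, steady states, synaptic decay) run on it.

## Layout engine

Layouts are animations: frame p is neuron p's position, frame 0 is the
initial state (all variables zero), and the user's equations describe the
transition between adjacent frames, evaluated with the target frame index
`p` for p = 1..n−1. Reading a variable yields its previous-frame value
unless an earlier equation of the same frame already assigned it. This
frame-0 convention is what makes a counter rule `x: x + 1` enumerate
0, 1, 2, … and a `mod/floor` grid fill row by row with unit spacing; the
grid formulas are our reconstruction of the documented behaviour, not a
transcription.

`rand()` draws uniform [0, 1) from one per-rule seeded stream. A minimum
distance is enforced by rejection: a violating candidate is redrawn — the
whole frame re-evaluated, refreshing every `rand()` of that frame — up to
10 000 attempts per point, after which a packing error is raised. A
deterministic rule that violates the constraint errors immediately, since
retrying cannot help. The random-box default side is 300 µm (the striatal
cube); min-distance post-conditions are verified in tests by exhaustive
O(n²) checks up to n = 1000.

## Connectivity generators

Generator scripts are plain text: metadata comments (`#PARNAME`, `#LOC`,
`#HASWEIGHT`, `#HASDELAY`) over an entry point `f(srclocs, dstlocs, …)`
returning `(src, dst[, delay][, weight])` tuples (delay before weight;
delays are ms). Scripts execute in a restricted namespace — arithmetic
builtins, `math`, `random.Random` — with no file or network access.
Results are persisted as fully explicit connection lists plus the recipe
in a dedicated XML namespace; `needs_regeneration` compares script text
byte-for-byte (a whitespace edit counts), parameter values and sizes, and
the cache key is the SHA-256 of those. Both built-ins (`fixed_radius`,
with delay = distance/velocity + base at a default velocity of 1 µm/ms,
and `gaussian_field`, connection probability and weight both
`exp(−d²/2σ²)`-shaped) are checked exactly against independent O(n²)
reimplementations in the tests.

## Basal-ganglia fixtures

The rate model is the classic channel-wise competition: cortex drives the
two striatal populations and the subthalamic nucleus; striatal D1 inhibits
the output nucleus, D2 inhibits the pallidum, the subthalamic nucleus
excites both, and the pallidum inhibits it back. All projections are
one-to-one channel-wise. Dopamine enters as `(1 + da)` / `(1 − da)` input
scaling on D1/D2 (tonic `da` = 0.2). Units are leaky integrators
`τ ȧ = −a + u` (τ = 25 ms) with output `clip(gain·(a − ε), 0, 1)`.

The published weight/gain/threshold table for this architecture lives
outside this codebase, so the shipped table is an explicit **placeholder**:
signs follow the topology (striatal/pallidal inhibitory, cortical and
subthalamic excitatory), inhibitory and cortico-striatal magnitudes sit
near 1 (sampled from [0.8, 1.2] in the property tests) and the
subthalamic-pathway magnitudes near 0.4 (sampled from [0.3, 0.5]). Within
those documented ranges focal striatal inhibition always dominates the
channel's own subthalamic excitation, so the disinhibition property —
driving one channel's cortex strictly lowers that channel's output-nucleus
activity at steady state — holds for every sign-consistent table the tests
draw. It is not guaranteed for arbitrary magnitudes (a strong enough
subthalamic pathway inverts it), which is why the ranges are part of the
fixture's definition.

The rate→spiking conversion is mechanical: each unit becomes 7
integrate-and-fire neurons (τ_m v̇ = −v + R·I, θ = 1, v_reset = 0,
t_ref = 2 ms — the equation form and these defaults are ours); one-to-one
channel links become within-channel all-to-all lists (fan-in 7², hence
weights ÷ 7); properties whose dimension is pA/nA are ×10, identified
mechanically by dimension, with the subthalamic intrinsic current the sole
exemption (we read the exemption as that one property, not all
subthalamic currents); τ_m ~ U(20, 30) ms per neuron, seeded; synapses are
exponential current synapses with τ_s = 4 ms; the analog cortical level u
maps to a regular spike train at u·100 Hz (the reconstruction consistent
with the 0.1 ↔ 10 Hz selection-threshold correspondence); and the D2
dopamine property is scaled by a factor (default 0.8) exposed as
configuration, since "slightly reduced" is not quantified anywhere. The
rate unit's output threshold ε re-enters as an intrinsic current −ε — a
placeholder mapping, like the weight table. With placeholder magnitudes
the spiking model is structurally and mechanically faithful but not
behaviourally calibrated; reproducing the published output traces would
require the published weight table and is out of scope.

The striatal-like fixture is synthetic: random-box layouts (300 µm cube,
10 µm minimum separation), standard two-variable point-neuron parameter
sets (regular-spiking projection neurons, fast-spiking interneurons), and
interneuron→projection-neuron connectivity from the `fixed_radius`
generator (100 µm radius, distance-derived delays). It exercises the
layout/generator/simulator chain; it does not model the published
dopamine- and gap-junction-extended striatal biophysics.

## Analysis

Rate estimation convolves spike trains with unit-area Gaussian kernels, so
the trace is in Hz and integrates to the spike count; σ defaults to
100 ms. For a regular train the mid-train estimate equals the train rate
up to ripple that is negligible at σ equal to the inter-spike interval —
the 10 Hz worked example recovers 10 Hz to < 10⁻⁶ relative. Selection
uses a strict `<` at the threshold (0.1 normalised, 10 Hz spiking), so a
trace sitting exactly on the threshold is not selected. Euler integration
biases a fitted exponential decay constant by ≈ dt/2: at dt = 0.01 ms the
4 ms synapse fits as 3.995 ms, inside the 1 % tolerance the worked example
uses. Plot helpers assert on the figure's data model (line data, raster
marks), not pixels.

## Problem sizes in the shipped runs

The default rate experiment is 6 channels × 6 populations for 6 s at
dt = 1 ms; property and determinism tests run shortened (0.25–1 s)
variants of the same model, chosen to keep each steady-state probe to
roughly a second of compute. Spiking checks use single components on the
bench (≤ 20 000 Euler steps) or 1–3-neuron chains; the striatal fixture
tests use 84 + 84 + 4 neurons. These sizes are the package's test-fixture
definitions, and the generators scale past them (layout min-distance is
O(n²)-verified to n = 1000; oracle equivalence to 200×150 coordinate
pairs).

## Known limitations

* Forward Euler only; no adaptive or implicit integrators, no
  event-time interpolation between steps.
* Analog connections cannot carry delays (delay 0 enforced); delays live
  on spike legs, quantised to ≥ 1 step.
* Port auto-wiring inside a projection picks the first kind/dimension
  compatible send/receive pair in declaration order; components with
  several compatible pairs need distinct dimensions to disambiguate.
* Connection lists may contain duplicate (src, dst) pairs; they are
  treated as independent multi-synapses.
* The weight filled by a `#HASWEIGHT` generator targets a named
  weight-update property (default `w`).
* A population emitting more than one spike per neuron per step collapses
  to one delivered event on each outgoing connection.
* No code-generation backends, version-control integration, GUI, or
  interoperability with other model-description languages.
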