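"""Built-in model fixtures.

Three families:

* a channel-wise basal-ganglia action-selection network of rate-coded leaky
  integrator units (cortex, striatal D1/D2, subthalamic nucleus, pallidal
  and nigral populations) with the classic disinhibition readout;
* a mechanical conversion of that rate model into a spiking network of
  leaky integrate-and-fire neurons (each rate unit widened to a small
  neuron group, one-to-one channel links replaced by within-channel
  all-to-all lists, weights divided by the fan-in, current-valued
  parameters rescaled, membrane time constants jittered, exponential
  current synapses added, and the analog cortical drive replaced by regular
  spike trains);
* a striatal-like microcircuit in a 300 um cube: random box layouts with a
  minimum distance and distance-based connectivity with distance-derived
  delays between two-variable (Izhikevich-style) point neurons.

The selection network's weight/gain/threshold table is a configuration
value with placeholder defaults whose signs follow the published topology
(striatal and pallidal projections inhibitory, cortical and subthalamic
excitatory); the magnitudes are ours, not a published set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .experiments import (
    ConstantInput,
    Experiment,
    Logger,
    RegularSpikeInput,
    TimeVaryingInput,
)
from .generators import FIXED_RADIUS_SCRIPT, parse_generator_metadata, run_generator
from .layouts import generate_layout, random_box_layout_rule
from .model_core import (
    Alias,
    Component,
    Dimension,
    Parameter,
    Port,
    Regime,
    StateVariable,
    Transition,
    duplicate_component,
)
from .network import (
    AllToAll,
    ComponentBinding,
    ConnectionList,
    FixedValue,
    GenericInput,
    Network,
    OneToOne,
    Population,
    Project,
    Projection,
    Synapse,
    UniformDistribution,
    ValueList,
    derive_seed,
)

__all__ = [
    "SELECTION_ROSTER",
    "SelectionNetworkConfig",
    "SnnConversionConfig",
    "StructureError",
    "build_selection_network",
    "convert_rate_to_snn",
    "build_striatal_like_fixture",
    "leaky_integrator_component",
    "lif_component",
    "exp_synapse_component",
    "spike_weight_component",
    "izhikevich_component",
]

PA = Dimension("pA")
MS = Dimension("ms")


# ---------------------------------------------------------------------------
# Component builders
# ---------------------------------------------------------------------------

def leaky_integrator_component(name: str = "lin",
                               dopamine: str | None = None) -> Component:
    """Rate-coded leaky integrator: tau a' = -a + u, output piecewise-linear
    clipped to [0, 1]. ``dopamine='d1'`` scales the input by (1 + da),
    ``'d2'`` by (1 - da)."""
    params = [Parameter("tau", MS), Parameter("gain"), Parameter("epsilon")]
    drive = "in"
    if dopamine == "d1":
        params.append(Parameter("da"))
        drive = "(1 + da) * in"
    elif dopamine == "d2":
        params.append(Parameter("da"))
        drive = "(1 - da) * in"
    return Component(
        name=name,
        kind="neuron_body",
        parameters=tuple(params),
        state_variables=(StateVariable("a"),),
        aliases=(Alias("out", "min(1, max(0, gain * (a - epsilon)))"),),
        ports=(
            Port("in", "receive", "analog", reduce_rule="sum"),
            Port("out", "send", "analog"),
        ),
        regimes=(Regime("integrating",
                        time_derivatives=((("a", f"(-a + {drive}) / tau")),)),),
    )


def relay_component(name: str = "analog_relay") -> Component:
    """Stateless pass-through: out = summed input (used for the cortex)."""
    return Component(
        name=name,
        kind="neuron_body",
        aliases=(Alias("out", "in"),),
        ports=(
            Port("in", "receive", "analog", reduce_rule="sum"),
            Port("out", "send", "analog"),
        ),
        regimes=(Regime("idle"),),
    )


def spike_relay_component(name: str = "spike_relay") -> Component:
    """Re-emits every received event (spike-source population driven by an
    experiment spike input)."""
    return Component(
        name=name,
        kind="neuron_body",
        ports=(
            Port("in", "receive", "event"),
            Port("spike", "send", "event"),
        ),
        regimes=(Regime(
            "idle",
            on_events=(Transition("in", "idle", emits=("spike",)),),
        ),),
    )


def rate_weight_component(name: str = "rate_weight") -> Component:
    """Weight update for the rate pathway: out = w * input."""
    return Component(
        name=name,
        kind="weight_update",
        parameters=(Parameter("w"),),
        aliases=(Alias("out", "w * in"),),
        ports=(
            Port("in", "receive", "analog"),
            Port("out", "send", "analog"),
        ),
        regimes=(Regime("idle"),),
    )


def rate_postsynapse_component(name: str = "rate_postsynapse") -> Component:
    """Postsynapse for the rate pathway: sums weighted inputs straight
    through."""
    return Component(
        name=name,
        kind="postsynapse",
        aliases=(Alias("out", "in"),),
        ports=(
            Port("in", "receive", "analog", reduce_rule="sum"),
            Port("out", "send", "analog"),
        ),
        regimes=(Regime("idle"),),
    )


def lif_component(name: str = "lif", dopamine: str | None = None) -> Component:
    """Leaky integrate-and-fire: tau_m v' = -v + R (I_syn + I_offset), spike
    and reset at threshold, absolute refractory period.

    Defaults used by the fixtures: theta = 1, v_reset = 0, t_ref = 2 ms.
    """
    params = [
        Parameter("tau_m", MS),
        Parameter("R"),
        Parameter("theta"),
        Parameter("v_reset"),
        Parameter("t_ref", MS),
        Parameter("I_offset", PA),
    ]
    drive = "in"
    if dopamine == "d1":
        params.append(Parameter("da"))
        drive = "(1 + da) * in"
    elif dopamine == "d2":
        params.append(Parameter("da"))
        drive = "(1 - da) * in"
    return Component(
        name=name,
        kind="neuron_body",
        parameters=tuple(params),
        state_variables=(StateVariable("v"), StateVariable("t_spike", MS)),
        ports=(
            Port("in", "receive", "analog", dimension=PA, reduce_rule="sum"),
            Port("spike", "send", "event"),
        ),
        regimes=(
            Regime(
                "integrating",
                time_derivatives=(
                    ("v", f"(-v + R * ({drive} + I_offset)) / tau_m"),),
                on_conditions=(Transition(
                    "v > theta", "refractory",
                    assignments=(("v", "v_reset"), ("t_spike", "t")),
                    emits=("spike",)),),
            ),
            Regime(
                "refractory",
                on_conditions=(Transition(
                    "t - t_spike >= t_ref", "integrating"),),
            ),
        ),
        initial_regime="integrating",
    )


def spike_weight_component(name: str = "spike_weight") -> Component:
    """Event-to-impulse weight update: each incoming spike emits an impulse
    carrying the weight w."""
    return Component(
        name=name,
        kind="weight_update",
        parameters=(Parameter("w"),),
        ports=(
            Port("spk", "receive", "event"),
            Port("w", "send", "impulse"),
        ),
        regimes=(Regime(
            "idle",
            on_events=(Transition("spk", "idle", emits=("w",)),),
        ),),
    )


def exp_synapse_component(name: str = "exp_synapse",
                          ) -> Component:
    """Exponentially decaying current synapse: tau_s I' = -I, each impulse
    adds its payload to I."""
    return Component(
        name=name,
        kind="postsynapse",
        parameters=(Parameter("tau_s", MS),),
        state_variables=(StateVariable("I", PA),),
        ports=(
            Port("inj", "receive", "impulse"),
            Port("I", "send", "analog", dimension=PA),
        ),
        regimes=(Regime(
            "decaying",
            time_derivatives=(("I", "-I / tau_s"),),
            on_impulses=(Transition("inj", "decaying",
                                    assignments=(("I", "I + inj"),)),),
        ),),
    )


def izhikevich_component(name: str = "izhikevich") -> Component:
    """Two-variable point neuron (quadratic membrane + recovery variable)."""
    return Component(
        name=name,
        kind="neuron_body",
        parameters=(Parameter("a"), Parameter("b"), Parameter("c"),
                    Parameter("d")),
        state_variables=(StateVariable("v", Dimension("mV")),
                         StateVariable("u")),
        ports=(
            Port("in", "receive", "analog", dimension=PA, reduce_rule="sum"),
            Port("spike", "send", "event"),
        ),
        regimes=(Regime(
            "spiking",
            time_derivatives=(
                ("v", "0.04 * v ^ 2 + 5 * v + 140 - u + in"),
                ("u", "a * (b * v - u)"),
            ),
            on_conditions=(Transition(
                "v >= 30", "spiking",
                assignments=(("v", "c"), ("u", "u + d")),
                emits=("spike",)),),
        ),),
    )


# ---------------------------------------------------------------------------
# Selection network (rate model)
# ---------------------------------------------------------------------------

#: Population-to-population connection roster; all top-down except the
#: pallido-subthalamic return projection.
SELECTION_ROSTER: tuple[tuple[str, str], ...] = (
    ("Cortex", "SD1"),
    ("Cortex", "SD2"),
    ("Cortex", "STN"),
    ("SD1", "SNr"),
    ("SD2", "GPe"),
    ("STN", "SNr"),
    ("STN", "GPe"),
    ("GPe", "STN"),
)

_DEFAULT_WEIGHTS: dict[tuple[str, str], float] = {
    # placeholder magnitudes; signs follow the topology
    ("Cortex", "SD1"): 1.0,
    ("Cortex", "SD2"): 1.0,
    ("Cortex", "STN"): 0.4,
    ("SD1", "SNr"): -1.0,
    ("SD2", "GPe"): -1.0,
    ("STN", "SNr"): 0.4,
    ("STN", "GPe"): 0.4,
    ("GPe", "STN"): -1.0,
}

_DEFAULT_EPSILONS = {
    "SD1": 0.2, "SD2": 0.2, "STN": -0.25, "GPe": -0.2, "SNr": -0.2,
}


@dataclass
class SelectionNetworkConfig:
    n_channels: int = 6
    tau: float = 25.0  # ms, leaky-integrator time constant
    dopamine: float = 0.2  # tonic dopamine level applied to both striata
    weights: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(_DEFAULT_WEIGHTS))
    gains: dict[str, float] = field(
        default_factory=lambda: {p: 1.0 for p in _DEFAULT_EPSILONS})
    epsilons: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_EPSILONS))
    with_default_experiment: bool = True


class ConfigError(ValueError):
    pass


def build_selection_network(
    cfg: SelectionNetworkConfig | None = None) -> Project:
    """Build the channel-wise action-selection project.

    Populations Cortex, SD1, SD2, STN, SNr and GPe, each sized n_channels,
    linked one-to-one channel-wise along the roster. The cortex is an
    analog relay exposing the input port for experiment drive.
    """
    cfg = cfg or SelectionNetworkConfig()
    missing = [edge for edge in SELECTION_ROSTER if edge not in cfg.weights]
    if missing:
        raise ConfigError(
            "weight table is missing entries: "
            + ", ".join(f"{s}->{d}" for s, d in missing))

    components = {
        "lin": leaky_integrator_component("lin"),
        "lin_d1": leaky_integrator_component("lin_d1", dopamine="d1"),
        "lin_d2": leaky_integrator_component("lin_d2", dopamine="d2"),
        "analog_relay": relay_component(),
        "rate_weight": rate_weight_component(),
        "rate_postsynapse": rate_postsynapse_component(),
    }

    comp_of = {"Cortex": "analog_relay", "SD1": "lin_d1", "SD2": "lin_d2",
               "STN": "lin", "GPe": "lin", "SNr": "lin"}

    def pop_properties(name: str):
        if name == "Cortex":
            return ()
        props = [
            ("tau", FixedValue(cfg.tau)),
            ("gain", FixedValue(cfg.gains[name])),
            ("epsilon", FixedValue(cfg.epsilons[name])),
            ("a", FixedValue(0.0)),
        ]
        if name in ("SD1", "SD2"):
            props.append(("da", FixedValue(cfg.dopamine)))
        return tuple(props)

    populations = tuple(
        Population(name, cfg.n_channels, comp_of[name], pop_properties(name))
        for name in ("Cortex", "SD1", "SD2", "STN", "SNr", "GPe"))

    projections = tuple(
        Projection(src, dst, (Synapse(
            OneToOne(),
            ComponentBinding("rate_weight",
                             (("w", FixedValue(cfg.weights[(src, dst)])),)),
            ComponentBinding("rate_postsynapse"),
        ),))
        for src, dst in SELECTION_ROSTER)

    network = Network("selection_network", populations, projections)

    experiments = []
    if cfg.with_default_experiment:
        experiments.append(default_selection_experiment(cfg.n_channels))
    return Project("selection", network, components, experiments)


def default_selection_experiment(n_channels: int) -> Experiment:
    """Step drive onto the first two channels; log the output nucleus on
    every channel and the first two D1 striatal units."""
    loggers = [
        Logger("snr_out", "SNr", "out", "analog"),
        Logger("sd1_first_two", "SD1", "out", "analog",
               indices=(0, 1) if n_channels >= 2 else (0,)),
    ]
    inputs: list = [
        TimeVaryingInput("Cortex", "in", ((1.0, 0.4), (3.0, 0.6)),
                         indices=(0,)),
    ]
    if n_channels >= 2:
        inputs.append(TimeVaryingInput("Cortex", "in", ((2.0, 0.6),),
                                       indices=(1,)))
    return Experiment(
        name="selection",
        network_ref="selection_network",
        duration=6.0,
        dt=1.0,
        description="step inputs on channels 1-2, outputs logged",
        inputs=tuple(inputs),
        loggers=tuple(loggers),
    )


# ---------------------------------------------------------------------------
# Rate-to-spiking conversion
# ---------------------------------------------------------------------------

@dataclass
class SnnConversionConfig:
    neurons_per_unit: int = 7
    weight_divisor: float = 7.0  # equals the within-channel fan-in
    current_scale: float = 10.0  # applied to pA/nA-valued properties
    current_scale_exempt: tuple[tuple[str, str], ...] = (("STN", "I_offset"),)
    tau_m_min: float = 20.0  # ms
    tau_m_max: float = 30.0  # ms
    synapse_tau: float = 4.0  # ms
    cortical_rate_scale: float = 100.0  # Hz per unit of analog drive
    d2_dopamine_factor: float = 0.8  # < 1: slightly reduced D2 dopamine
    theta: float = 1.0
    v_reset: float = 0.0
    t_ref: float = 2.0  # ms
    dt: float = 0.1  # ms for converted experiments

    def __post_init__(self):
        if self.neurons_per_unit < 1:
            raise ValueError("neurons_per_unit must be >= 1")
        if not 0 < self.d2_dopamine_factor <= 1:
            raise ValueError("d2_dopamine_factor must be in (0, 1]")


class StructureError(ValueError):
    pass


def _expand_indices(indices, m: int, n_channels: int):
    if indices is None:
        return None
    return tuple(c * m + i for c in indices for i in range(m))


def convert_rate_to_snn(project: Project,
                        cfg: SnnConversionConfig | None = None,
                        seed: int = 0) -> Project:
    """Convert a selection-network project into its spiking counterpart.

    Every rate unit becomes ``neurons_per_unit`` integrate-and-fire neurons;
    one-to-one channel links become within-channel all-to-all connection
    lists; weights are divided by ``weight_divisor``; properties carrying a
    current dimension (pA/nA) are multiplied by ``current_scale`` except the
    exempt (population, property) pairs; membrane time constants are drawn
    per neuron from U(tau_m_min, tau_m_max); synapses become exponential
    current synapses with ``synapse_tau``; the analog cortical drive becomes
    regular spike trains at ``cortical_rate_scale`` Hz per drive unit; and
    the D2 dopamine property is scaled by ``d2_dopamine_factor``.
    """
    cfg = cfg or SnnConversionConfig()
    m = cfg.neurons_per_unit
    net = project.network
    if not net.populations:
        raise StructureError("source project has no populations")
    n_channels = net.populations[0].size
    if any(p.size != n_channels for p in net.populations):
        raise StructureError(
            "source populations must share one channel count")
    for proj in net.projections:
        for syn in proj.synapses:
            if not isinstance(syn.connectivity, OneToOne):
                raise StructureError(
                    f"{proj.source}->{proj.destination}: conversion expects "
                    "one-to-one channel links")

    components = {
        "lif": lif_component("lif"),
        "lif_d1": lif_component("lif_d1", dopamine="d1"),
        "lif_d2": lif_component("lif_d2", dopamine="d2"),
        "spike_relay": spike_relay_component(),
        "spike_weight": spike_weight_component(),
        "exp_synapse": exp_synapse_component(),
    }
    lif_kind = {"lin": "lif", "lin_d1": "lif_d1", "lin_d2": "lif_d2"}

    def fixed_of(pop: Population, name: str, default: float = 0.0) -> float:
        for pname, pval in pop.properties:
            if pname == name and isinstance(pval, FixedValue):
                return pval.value
        return default

    populations = []
    exempt = set(cfg.current_scale_exempt)
    for pop in net.populations:
        size = pop.size * m
        if pop.component_ref not in lif_kind:
            # relay populations (the cortical drive) become spike relays
            populations.append(replace(
                pop, size=size, component_ref="spike_relay", properties=()))
            continue
        comp_ref = lif_kind[pop.component_ref]
        comp = components[comp_ref]
        dims = {p.name: p.dimension.unit_label for p in comp.parameters}
        props: list[tuple[str, object]] = [
            ("tau_m", UniformDistribution(
                cfg.tau_m_min, cfg.tau_m_max,
                derive_seed(seed, "tau_m", pop.name))),
            ("R", FixedValue(1.0)),
            ("theta", FixedValue(cfg.theta)),
            ("v_reset", FixedValue(cfg.v_reset)),
            ("t_ref", FixedValue(cfg.t_ref)),
            # the rate unit's output threshold becomes an intrinsic current
            ("I_offset", FixedValue(-fixed_of(pop, "epsilon"))),
        ]
        if comp_ref in ("lif_d1", "lif_d2"):
            da = fixed_of(pop, "da")
            if comp_ref == "lif_d2":
                da *= cfg.d2_dopamine_factor
            props.append(("da", FixedValue(da)))
        scaled = []
        for pname, pval in props:
            if (dims.get(pname) in ("pA", "nA")
                    and (pop.name, pname) not in exempt
                    and isinstance(pval, FixedValue)):
                pval = FixedValue(pval.value * cfg.current_scale)
            scaled.append((pname, pval))
        populations.append(Population(pop.name, size, comp_ref,
                                      tuple(scaled), pop.layout_ref,
                                      pop.colour))

    def within_channel_all_to_all() -> ConnectionList:
        triplets = []
        for c in range(n_channels):
            base = c * m
            for i in range(m):
                for j in range(m):
                    triplets.append((base + i, base + j, 0.0))
        return ConnectionList(tuple(triplets))

    projections = []
    for proj in net.projections:
        syn = proj.synapses[0]
        w = None
        for pname, pval in syn.weight_update.properties:
            if pname == "w" and isinstance(pval, FixedValue):
                w = pval.value
        if w is None:
            raise StructureError(
                f"{proj.source}->{proj.destination}: no fixed weight to scale")
        projections.append(Projection(proj.source, proj.destination, (Synapse(
            within_channel_all_to_all(),
            ComponentBinding("spike_weight",
                             (("w", FixedValue(w / cfg.weight_divisor)),)),
            ComponentBinding("exp_synapse",
                             (("tau_s", FixedValue(cfg.synapse_tau)),)),
        ),)))

    network = Network(f"{net.name}_snn", tuple(populations),
                      tuple(projections), net.generic_inputs)

    experiments = []
    for exp in project.experiments:
        inputs: list = []
        for spec in exp.inputs:
            idx = _expand_indices(spec.indices, m, n_channels)
            if isinstance(spec, ConstantInput):
                if spec.value > 0:
                    inputs.append(RegularSpikeInput(
                        spec.target, "in",
                        rate=spec.value * cfg.cortical_rate_scale,
                        start=0.0, stop=exp.duration, indices=idx))
            elif isinstance(spec, TimeVaryingInput):
                bounds = [t for t, _ in spec.steps] + [exp.duration]
                for (t0, value), t1 in zip(spec.steps, bounds[1:]):
                    if value > 0:
                        inputs.append(RegularSpikeInput(
                            spec.target, "in",
                            rate=value * cfg.cortical_rate_scale,
                            start=t0, stop=t1, indices=idx))
            else:
                inputs.append(replace(spec, indices=idx))
        loggers = []
        for logger in exp.loggers:
            idx = _expand_indices(logger.indices, m, n_channels)
            if logger.kind == "analog" and logger.port == "out":
                loggers.append(Logger(logger.name, logger.target, "spike",
                                      "event", idx))
            else:
                loggers.append(replace(logger, indices=idx))
        experiments.append(replace(
            exp, name=f"{exp.name}_snn", network_ref=network.name, dt=cfg.dt,
            inputs=tuple(inputs), loggers=tuple(loggers),
            property_changes=()))

    return Project(f"{project.name}_snn", network, components, experiments,
                   dict(project.layouts))


# ---------------------------------------------------------------------------
# Striatal-like cube fixture
# ---------------------------------------------------------------------------

def build_striatal_like_fixture(
    n_msn_d1: int = 84,
    n_msn_d2: int = 84,
    n_fsi: int = 4,
    side: float = 300.0,
    seed: int = 0,
    min_distance: float = 10.0,
    radius: float = 100.0,
    velocity: float = 1.0,  # um/ms, delay = distance / velocity
) -> Project:
    """Synthetic striatal-like microcircuit in a cube of the given side.

    Populations of two-variable point neurons placed by seeded random box
    layouts with a minimum separation; fast-spiking interneurons project to
    both spiny populations whenever the somatic distance is within
    ``radius``, with conduction delays derived from distance. The
    connection lists carry their generation recipes.
    """
    base = izhikevich_component("izhikevich")
    components = {
        "izhikevich": base,
        "izh_msn": duplicate_component(base, "izh_msn"),
        "izh_fsi": duplicate_component(base, "izh_fsi"),
        "spike_weight": spike_weight_component(),
        "exp_synapse": exp_synapse_component(),
    }

    specs = [
        ("MSN_D1", n_msn_d1, "izh_msn",
         {"a": 0.02, "b": 0.2, "c": -65.0, "d": 8.0}),
        ("MSN_D2", n_msn_d2, "izh_msn",
         {"a": 0.02, "b": 0.2, "c": -65.0, "d": 8.0}),
        ("FSI", n_fsi, "izh_fsi",
         {"a": 0.1, "b": 0.2, "c": -65.0, "d": 2.0}),
    ]
    layouts = {}
    populations = []
    coords = {}
    for name, n, comp_ref, params in specs:
        if n < 1:
            raise ValueError(f"population {name} must have >= 1 neurons")
        rule = random_box_layout_rule(
            side, derive_seed(seed, "layout", name), min_distance,
            name=f"{name}_box")
        layouts[rule.name] = rule
        coords[name] = generate_layout(rule, n)
        props = tuple(
            [(k, FixedValue(v)) for k, v in params.items()]
            + [("v", FixedValue(-65.0)), ("u", FixedValue(-13.0))])
        populations.append(Population(name, n, comp_ref, props,
                                      layout_ref=rule.name))

    script = parse_generator_metadata(FIXED_RADIUS_SCRIPT)
    projections = []
    for dst in ("MSN_D1", "MSN_D2"):
        clist = run_generator(script, coords["FSI"], coords[dst],
                              (radius, velocity, 0.0))
        projections.append(Projection("FSI", dst, (Synapse(
            clist,
            ComponentBinding("spike_weight", (("w", FixedValue(-2.0)),)),
            ComponentBinding("exp_synapse", (("tau_s", FixedValue(4.0)),)),
        ),)))

    network = Network("striatal_like", tuple(populations), tuple(projections))
    experiment = Experiment(
        name="fsi_drive",
        network_ref="striatal_like",
        duration=0.2,
        dt=0.1,
        description="constant current drive onto the interneurons",
        inputs=(ConstantInput("FSI", "in", 10.0),),
        loggers=(
            Logger("fsi_spikes", "FSI", "spike", "event"),
            Logger("msn_v", "MSN_D1", "v", "analog",
                   indices=(0, 1) if n_msn_d1 >= 2 else (0,)),
        ),
    )
    return Project("striatal_like", network, components, [experiment],
                   layouts)
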