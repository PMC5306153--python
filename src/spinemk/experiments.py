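"""Experiment layer: stimuli, recordings and property overrides.

An experiment is the model-independent description of a run — duration and
step size, input signals, loggers and property changes — bound to a network
by name, the way an experimental paradigm is applied to an animal without
altering the animal. Durations and input times are seconds; the integration
step dt is milliseconds.

Inputs: ``constant`` holds a value for the whole run; ``time_varying`` is a
piecewise-constant step signal (value of the latest step at or before t,
zero before the first — no interpolation); ``regular_spikes`` delivers
spikes at start + k/rate for k = 0, 1, ... while inside [start, stop).
"""

from __future__ import annotations

import copy
import xml.etree.ElementTree as ET
from dataclasses import dataclass, replace

import numpy as np

from .network import (
    Network,
    PropertyValue,
    _property_element,
    _read_property,
)

__all__ = [
    "ConstantInput",
    "TimeVaryingInput",
    "RegularSpikeInput",
    "InputSpec",
    "Logger",
    "PropertyChange",
    "Experiment",
    "apply_property_changes",
    "input_value",
    "spike_times",
    "validate_experiment",
    "read_experiment_xml",
    "write_experiment_xml",
    "write_log_metadata",
]


@dataclass(frozen=True)
class ConstantInput:
    target: str  # population name
    port: str
    value: float
    indices: tuple[int, ...] | None = None  # None = whole population


@dataclass(frozen=True)
class TimeVaryingInput:
    target: str
    port: str
    steps: tuple[tuple[float, float], ...]  # (time s, value), held constant
    indices: tuple[int, ...] | None = None

    def __post_init__(self):
        times = [t for t, _ in self.steps]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("time points must be strictly increasing")


@dataclass(frozen=True)
class RegularSpikeInput:
    target: str
    port: str
    rate: float  # Hz
    start: float  # s
    stop: float  # s
    indices: tuple[int, ...] | None = None

    def __post_init__(self):
        if self.rate < 0:
            raise ValueError("rate must be >= 0")


InputSpec = ConstantInput | TimeVaryingInput | RegularSpikeInput


@dataclass(frozen=True)
class Logger:
    """Records an analog quantity (port or state variable) or an event port
    for a population, optionally restricted to an index subset."""

    name: str
    target: str  # population name
    port: str  # port or state-variable name
    kind: str  # analog | event
    indices: tuple[int, ...] | None = None


@dataclass(frozen=True)
class PropertyChange:
    population: str
    property: str
    value: PropertyValue


@dataclass(frozen=True)
class Experiment:
    name: str
    network_ref: str
    duration: float  # s
    dt: float  # ms
    description: str = ""
    inputs: tuple[InputSpec, ...] = ()
    loggers: tuple[Logger, ...] = ()
    property_changes: tuple[PropertyChange, ...] = ()

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")

    def n_steps(self) -> int:
        return int(round(self.duration * 1000.0 / self.dt))


def apply_property_changes(net: Network, experiment: Experiment) -> Network:
    """Return a resolved copy of the network with the experiment's property
    overrides applied; the original network is untouched."""
    pops = list(net.populations)
    for change in experiment.property_changes:
        for i, pop in enumerate(pops):
            if pop.name == change.population:
                names = [n for n, _ in pop.properties]
                if change.property in names:
                    new_props = tuple(
                        (n, change.value if n == change.property else v)
                        for n, v in pop.properties)
                else:
                    new_props = (*pop.properties,
                                 (change.property, change.value))
                pops[i] = replace(pop, properties=new_props)
                break
        else:
            raise ValueError(
                f"property change targets unknown population "
                f"{change.population!r} (property {change.property!r})")
    return replace(net, populations=tuple(pops))


def input_value(spec: InputSpec, t: float) -> float:
    """Analog input value at time t (seconds)."""
    if isinstance(spec, ConstantInput):
        return spec.value
    if isinstance(spec, TimeVaryingInput):
        value = 0.0
        for step_t, step_v in spec.steps:
            if step_t <= t:
                value = step_v
            else:
                break
        return value
    raise TypeError(f"no analog value for input {spec!r}")


def spike_times(spec: RegularSpikeInput) -> np.ndarray:
    """Spike times (s): {start + k/rate : k >= 0} intersected with
    [start, stop)."""
    if spec.rate <= 0 or spec.stop <= spec.start:
        return np.empty(0)
    period = 1.0 / spec.rate
    n = int(np.ceil((spec.stop - spec.start) / period))
    times = spec.start + period * np.arange(n + 1)
    return times[times < spec.stop - 1e-12]


def validate_experiment(experiment: Experiment, net: Network,
                        components: dict) -> list[str]:
    """Return human-readable problems; empty list when everything resolves."""
    problems: list[str] = []

    def component_of(pop_name: str):
        pop = net.population(pop_name)
        if pop is None:
            problems.append(f"unknown population {pop_name!r}")
            return None
        comp = components.get(pop.component_ref)
        if comp is None:
            problems.append(f"population {pop_name!r} has dangling component")
        return comp

    for spec in experiment.inputs:
        comp = component_of(spec.target)
        if comp is None:
            continue
        port = comp.port(spec.port)
        if port is None or port.direction != "receive":
            problems.append(
                f"input targets missing receive port {spec.port!r} on "
                f"{spec.target!r}")
            continue
        if isinstance(spec, RegularSpikeInput) and port.kind != "event":
            problems.append(
                f"spike input targets non-event port {spec.port!r}")
        if isinstance(spec, (ConstantInput, TimeVaryingInput)) \
                and port.kind != "analog":
            problems.append(
                f"analog input targets non-analog port {spec.port!r}")

    for logger in experiment.loggers:
        comp = component_of(logger.target)
        if comp is None:
            continue
        port = comp.port(logger.port)
        if logger.kind == "event":
            if port is None or port.kind != "event" or port.direction != "send":
                problems.append(
                    f"event logger {logger.name!r} targets "
                    f"{logger.port!r} which is not an event send port")
        else:
            analog_ok = (
                logger.port in comp.state_names()
                or logger.port in comp.alias_names()
                or (port is not None and port.kind == "analog"))
            if not analog_ok:
                problems.append(
                    f"analog logger {logger.name!r} targets non-analog "
                    f"quantity {logger.port!r}")

    for change in experiment.property_changes:
        pop = net.population(change.population)
        if pop is None:
            problems.append(
                f"property change targets unknown population "
                f"{change.population!r}")
            continue
        comp = components.get(pop.component_ref)
        if comp is not None and change.property not in comp.property_names():
            problems.append(
                f"property change targets missing property "
                f"{change.property!r} on {change.population!r}")
    return problems


# ---------------------------------------------------------------------------
# XML
# ---------------------------------------------------------------------------

class ExperimentParseError(ValueError):
    pass


def _indices_attr(indices: tuple[int, ...] | None) -> dict:
    if indices is None:
        return {}
    return {"indices": ",".join(str(i) for i in indices)}


def _read_indices(el: ET.Element) -> tuple[int, ...] | None:
    raw = el.get("indices")
    if raw is None or raw == "":
        return None
    return tuple(int(s) for s in raw.split(","))


def write_experiment_xml(experiment: Experiment) -> str:
    root = ET.Element("Experiment", {"name": experiment.name,
                                     "description": experiment.description})
    ET.SubElement(root, "Model",
                  {"network_layer_url": f"{experiment.network_ref}.xml"})
    ET.SubElement(root, "Simulation", {"duration": repr(experiment.duration),
                                       "dt": repr(experiment.dt)})
    for spec in experiment.inputs:
        if isinstance(spec, ConstantInput):
            ET.SubElement(root, "ConstantInput", {
                "target": spec.target, "port": spec.port,
                "value": repr(spec.value), **_indices_attr(spec.indices)})
        elif isinstance(spec, TimeVaryingInput):
            el = ET.SubElement(root, "TimeVaryingInput", {
                "target": spec.target, "port": spec.port,
                **_indices_attr(spec.indices)})
            for t, v in spec.steps:
                ET.SubElement(el, "TimePointValue",
                              {"time": repr(t), "value": repr(v)})
        elif isinstance(spec, RegularSpikeInput):
            ET.SubElement(root, "RegularSpikeInput", {
                "target": spec.target, "port": spec.port,
                "rate": repr(spec.rate), "start": repr(spec.start),
                "stop": repr(spec.stop), **_indices_attr(spec.indices)})
    for logger in experiment.loggers:
        ET.SubElement(root, "LogOutput", {
            "name": logger.name, "target": logger.target,
            "port": logger.port, "type": logger.kind,
            **_indices_attr(logger.indices)})
    for change in experiment.property_changes:
        el = ET.SubElement(root, "PropertyChange",
                           {"population": change.population,
                            "property": change.property})
        el.append(_property_element(change.property, change.value))
    ET.indent(root)
    return ET.tostring(root, encoding="unicode")


def read_experiment_xml(text: str) -> Experiment:
    try:
        root = ET.fromstring(text)
    except ET.ParseError as exc:
        raise ExperimentParseError(f"malformed XML: {exc}") from exc
    if root.tag != "Experiment":
        raise ExperimentParseError(f"unknown root tag {root.tag!r}")
    network_ref = ""
    duration = dt = None
    inputs: list[InputSpec] = []
    loggers: list[Logger] = []
    changes: list[PropertyChange] = []
    for el in root:
        if el.tag == "Model":
            url = el.get("network_layer_url", "")
            network_ref = url[:-4] if url.endswith(".xml") else url
        elif el.tag == "Simulation":
            duration = float(el.get("duration", "0"))
            dt = float(el.get("dt", "0.1"))
        elif el.tag == "ConstantInput":
            inputs.append(ConstantInput(
                el.get("target", ""), el.get("port", ""),
                float(el.get("value", "0")), _read_indices(el)))
        elif el.tag == "TimeVaryingInput":
            steps = tuple((float(c.get("time", "0")), float(c.get("value", "0")))
                          for c in el if c.tag == "TimePointValue")
            inputs.append(TimeVaryingInput(
                el.get("target", ""), el.get("port", ""), steps,
                _read_indices(el)))
        elif el.tag == "RegularSpikeInput":
            inputs.append(RegularSpikeInput(
                el.get("target", ""), el.get("port", ""),
                float(el.get("rate", "0")), float(el.get("start", "0")),
                float(el.get("stop", "0")), _read_indices(el)))
        elif el.tag == "LogOutput":
            loggers.append(Logger(
                el.get("name", ""), el.get("target", ""),
                el.get("port", ""), el.get("type", "analog"),
                _read_indices(el)))
        elif el.tag == "PropertyChange":
            prop = el.find("Property")
            if prop is None:
                raise ExperimentParseError("PropertyChange without Property")
            _, value = _read_property(prop)
            changes.append(PropertyChange(
                el.get("population", ""), el.get("property", ""), value))
        else:
            raise ExperimentParseError(f"unknown tag {el.tag!r}")
    if duration is None or dt is None:
        raise ExperimentParseError("missing Simulation element")
    return Experiment(
        name=root.get("name", ""),
        network_ref=network_ref,
        duration=duration,
        dt=dt,
        description=root.get("description", ""),
        inputs=tuple(inputs),
        loggers=tuple(loggers),
        property_changes=tuple(changes),
    )


def write_log_metadata(logger: Logger, record_count: int, dt: float,
                       data_path: str, n_columns: int | None = None) -> str:
    """Descriptor XML written alongside each data file: the source, type
    and quantity of data logged."""
    tag = "EventLog" if logger.kind == "event" else "AnalogLog"
    attrs = {
        "name": logger.name,
        "target": logger.target,
        "port": logger.port,
        "data_file": data_path,
        "dt": repr(dt),
    }
    if logger.kind == "event":
        attrs["events"] = str(record_count)
    else:
        attrs["rows"] = str(record_count)
        attrs["columns"] = str(n_columns if n_columns is not None else 1)
        attrs["format"] = "float64-le-row-major"
    if logger.indices is not None:
        attrs["indices"] = ",".join(str(i) for i in logger.indices)
    root = ET.Element("LogReport")
    ET.SubElement(root, tag, attrs)
    ET.indent(root)
    return ET.tostring(root, encoding="unicode")
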