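"""Network layer: populations, projections, synapses, generic inputs.

A network binds named populations to components and wires them with
projections. Each projection holds at least one synapse, and a synapse is
the triple (connectivity scheme, weight-update component, postsynapse
component). Property values configure component parameters/state per
population, either as fixed numbers, explicit per-neuron lists, or seeded
uniform/normal draws.

Conventions: neuron indices are 0-based everywhere; delays are milliseconds;
a missing per-property seed is derived from the project master seed by
stable hashing of the property path (SHA-256, truncated below 2**31).
"""

from __future__ import annotations

import copy
import hashlib
import os
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace

import numpy as np

from .model_core import (
    Component,
    Violation,
    check_port_compatibility,
    read_component_xml,
    validate_component,
    write_component_xml,
)

__all__ = [
    "ANNOTATION_NS",
    "FixedValue",
    "ValueList",
    "UniformDistribution",
    "NormalDistribution",
    "PropertyValue",
    "OneToOne",
    "AllToAll",
    "FixedProbability",
    "ConnectionList",
    "ComponentBinding",
    "Population",
    "Synapse",
    "Projection",
    "GenericInput",
    "Network",
    "Project",
    "derive_seed",
    "sample_property",
    "instantiate_connectivity",
    "copy_properties",
    "validate_network",
    "read_network_xml",
    "write_network_xml",
    "read_project",
    "write_project",
]

#: Dedicated namespace for tool-specific extras so foreign readers can skip it.
ANNOTATION_NS = "https://spinemk.invalid/annotations/v1"
ET.register_namespace("smk", ANNOTATION_NS)


def derive_seed(master_seed: int, *path: object) -> int:
    """Stable sub-seed from a master seed and a path of labels (< 2**31)."""
    h = hashlib.sha256(
        ("/".join(str(p) for p in (master_seed, *path))).encode()
    ).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


# ---------------------------------------------------------------------------
# Property values
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixedValue:
    value: float


@dataclass(frozen=True)
class ValueList:
    items: tuple[tuple[int, float], ...]  # (index, value)


@dataclass(frozen=True)
class UniformDistribution:
    minimum: float
    maximum: float
    seed: int | None = None

    def __post_init__(self):
        if not self.minimum < self.maximum:
            raise ValueError("uniform distribution requires minimum < maximum")


@dataclass(frozen=True)
class NormalDistribution:
    mean: float
    variance: float
    seed: int | None = None

    def __post_init__(self):
        if self.variance < 0:
            raise ValueError("normal distribution requires variance >= 0")


PropertyValue = FixedValue | ValueList | UniformDistribution | NormalDistribution


class CoverageError(ValueError):
    """A ValueList does not cover exactly the indices 0..n-1."""


def sample_property(value: PropertyValue, n: int, seed: int) -> np.ndarray:
    """Realise a property as n per-neuron numbers.

    Identical (value, n, seed) gives identical output; a seed stored on the
    distribution itself takes precedence over the argument.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if isinstance(value, FixedValue):
        return np.full(n, float(value.value))
    if isinstance(value, ValueList):
        indices = [i for i, _ in value.items]
        if sorted(indices) != list(range(n)):
            raise CoverageError(
                f"value list must cover indices 0..{n - 1} exactly once"
            )
        out = np.empty(n)
        for i, v in value.items:
            out[i] = v
        return out
    rng = np.random.default_rng(value.seed if value.seed is not None else seed)
    if isinstance(value, UniformDistribution):
        return rng.uniform(value.minimum, value.maximum, n)
    if isinstance(value, NormalDistribution):
        return rng.normal(value.mean, np.sqrt(value.variance), n)
    raise TypeError(f"not a property value: {value!r}")


# ---------------------------------------------------------------------------
# Connectivity schemes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OneToOne:
    pass


@dataclass(frozen=True)
class AllToAll:
    pass


@dataclass(frozen=True)
class FixedProbability:
    p: float
    seed: int | None = None
    allow_self: bool = False

    def __post_init__(self):
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("probability must be in [0, 1]")


@dataclass(frozen=True)
class ConnectionList:
    """Explicit connectivity: (source, destination, delay-ms) triplets."""

    triplets: tuple[tuple[int, int, float], ...]
    weights: tuple[float, ...] | None = None
    recipe: object | None = None  # GenerationRecipe, attached by conn generators

    def __post_init__(self):
        if self.weights is not None and len(self.weights) != len(self.triplets):
            raise ValueError("weights must parallel the triplet list")

    def __len__(self):
        return len(self.triplets)

    def sources(self) -> np.ndarray:
        return np.array([t[0] for t in self.triplets], dtype=np.int64)

    def destinations(self) -> np.ndarray:
        return np.array([t[1] for t in self.triplets], dtype=np.int64)

    def delays(self) -> np.ndarray:
        return np.array([t[2] for t in self.triplets], dtype=np.float64)


ConnectivityScheme = OneToOne | AllToAll | FixedProbability | ConnectionList


def instantiate_connectivity(
    scheme: ConnectivityScheme,
    n_src: int,
    n_dst: int,
    seed: int = 0,
    same_population: bool = False,
) -> ConnectionList:
    """Expand a connectivity scheme to an explicit connection list.

    Pair order is source-major, destination-minor. ``fixed_probability``
    excludes self-pairs when source and destination are the same population
    (override with the scheme's ``allow_self`` flag); draws for excluded
    pairs are still consumed so exclusion does not shift the stream.
    """
    if n_src < 1 or n_dst < 1:
        raise ValueError("population sizes must be >= 1")
    if isinstance(scheme, OneToOne):
        if n_src != n_dst:
            raise ValueError(
                f"one_to_one requires equal sizes, got {n_src} != {n_dst}"
            )
        return ConnectionList(tuple((i, i, 0.0) for i in range(n_src)))
    if isinstance(scheme, AllToAll):
        return ConnectionList(
            tuple((i, j, 0.0) for i in range(n_src) for j in range(n_dst))
        )
    if isinstance(scheme, FixedProbability):
        rng = np.random.default_rng(
            scheme.seed if scheme.seed is not None else seed
        )
        draws = rng.random((n_src, n_dst))
        mask = draws < scheme.p
        if same_population and not scheme.allow_self:
            np.fill_diagonal(mask, False)
        src, dst = np.nonzero(mask)
        return ConnectionList(
            tuple((int(i), int(j), 0.0) for i, j in zip(src, dst))
        )
    if isinstance(scheme, ConnectionList):
        return scheme
    raise TypeError(f"not a connectivity scheme: {scheme!r}")


# ---------------------------------------------------------------------------
# Network structure
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ComponentBinding:
    """A component reference plus its property configuration."""

    component_ref: str
    properties: tuple[tuple[str, PropertyValue], ...] = ()

    def property_dict(self) -> dict[str, PropertyValue]:
        return dict(self.properties)


@dataclass(frozen=True)
class Population:
    name: str
    size: int
    component_ref: str
    properties: tuple[tuple[str, PropertyValue], ...] = ()
    layout_ref: str | None = None
    colour: str | None = None

    def property_dict(self) -> dict[str, PropertyValue]:
        return dict(self.properties)


@dataclass(frozen=True)
class Synapse:
    connectivity: ConnectivityScheme
    weight_update: ComponentBinding
    postsynapse: ComponentBinding


@dataclass(frozen=True)
class Projection:
    source: str
    destination: str
    synapses: tuple[Synapse, ...]


@dataclass(frozen=True)
class GenericInput:
    """A direct port-to-port connection outside the projection structure."""

    source: str
    source_port: str
    destination: str
    destination_port: str
    connectivity: ConnectivityScheme


@dataclass(frozen=True)
class Network:
    name: str
    populations: tuple[Population, ...] = ()
    projections: tuple[Projection, ...] = ()
    generic_inputs: tuple[GenericInput, ...] = ()

    def population(self, name: str) -> Population | None:
        for p in self.populations:
            if p.name == name:
                return p
        return None


@dataclass
class Project:
    """A working-directory's worth of model: one network, its components,
    experiments and layout definitions."""

    name: str
    network: Network
    components: dict[str, Component] = field(default_factory=dict)
    experiments: list = field(default_factory=list)  # of experiments.Experiment
    layouts: dict[str, object] = field(default_factory=dict)  # of LayoutRule

    def __eq__(self, other):
        return (
            isinstance(other, Project)
            and self.name == other.name
            and self.network == other.network
            and self.components == other.components
            and self.experiments == other.experiments
            and self.layouts == other.layouts
        )


def copy_properties(
    src: Population, dst: Population
) -> tuple[Population, list[str]]:
    """Copy the property configuration from one population to another.

    Every property name present on both populations takes src's value on the
    returned copy of dst; names not shared are left unchanged and returned
    as the skipped list. Components may differ.
    """
    src_props = src.property_dict()
    new_props = []
    copied = set()
    for name, value in dst.properties:
        if name in src_props:
            new_props.append((name, src_props[name]))
            copied.add(name)
        else:
            new_props.append((name, value))
    skipped = sorted(set(src_props) - copied)
    return replace(dst, properties=tuple(new_props)), skipped


def validate_network(
    net: Network, components: dict[str, Component]
) -> list[Violation]:
    """Cross-layer validation; returns a violation list, raises nothing."""
    out: list[Violation] = []
    names = [p.name for p in net.populations]
    if len(set(names)) != len(names):
        out.append(Violation(net.name, "unique-population-names",
                             "duplicate population names"))
    sizes = {p.name: p.size for p in net.populations}

    def check_binding(binding: ComponentBinding, where: str, expected_kind: str,
                      n: int):
        comp = components.get(binding.component_ref)
        if comp is None:
            out.append(Violation(where, "component-ref",
                                 f"unknown component {binding.component_ref!r}"))
            return
        if comp.kind != expected_kind:
            out.append(Violation(
                where, "component-kind",
                f"{binding.component_ref!r} has kind {comp.kind!r}, "
                f"expected {expected_kind!r}"))
        allowed = set(comp.property_names())
        for pname, pval in binding.properties:
            if pname not in allowed:
                out.append(Violation(
                    where, "property-exists",
                    f"property {pname!r} not on component {comp.name!r}"))
            _check_property_value(pval, n, where, pname, out)

    for pop in net.populations:
        if pop.size < 1:
            out.append(Violation(pop.name, "population-size",
                                 f"size must be >= 1, got {pop.size}"))
        comp = components.get(pop.component_ref)
        if comp is None:
            out.append(Violation(pop.name, "component-ref",
                                 f"unknown component {pop.component_ref!r}"))
        else:
            allowed = set(comp.property_names())
            for pname, pval in pop.properties:
                if pname not in allowed:
                    out.append(Violation(
                        pop.name, "property-exists",
                        f"property {pname!r} not on component {comp.name!r}"))
                _check_property_value(pval, pop.size, pop.name, pname, out)

    for proj in net.projections:
        where = f"{proj.source}->{proj.destination}"
        if proj.source not in sizes:
            out.append(Violation(where, "population-ref",
                                 f"unknown source population {proj.source!r}"))
        if proj.destination not in sizes:
            out.append(Violation(where, "population-ref",
                                 f"unknown destination population "
                                 f"{proj.destination!r}"))
        if not proj.synapses:
            out.append(Violation(where, "at-least-one-synapse",
                                 "projection has no synapses"))
        if proj.source not in sizes or proj.destination not in sizes:
            continue  # size-dependent checks would only cascade
        n_src = sizes[proj.source]
        n_dst = sizes[proj.destination]
        for k, syn in enumerate(proj.synapses):
            swhere = f"{where}[{k}]"
            check_binding(syn.weight_update, swhere, "weight_update",
                          _scheme_count(syn.connectivity, n_src, n_dst))
            check_binding(syn.postsynapse, swhere, "postsynapse", n_dst)
            _check_scheme(syn.connectivity, n_src, n_dst, swhere, out)

    for gi in net.generic_inputs:
        where = f"input {gi.source}:{gi.source_port}->" \
                f"{gi.destination}:{gi.destination_port}"
        src_pop = net.population(gi.source)
        dst_pop = net.population(gi.destination)
        if src_pop is None or dst_pop is None:
            out.append(Violation(where, "population-ref",
                                 "generic input references unknown population"))
            continue
        src_comp = components.get(src_pop.component_ref)
        dst_comp = components.get(dst_pop.component_ref)
        if src_comp is None or dst_comp is None:
            continue  # dangling component refs already reported
        sp = src_comp.port(gi.source_port)
        rp = dst_comp.port(gi.destination_port)
        if sp is None or sp.direction != "send":
            out.append(Violation(where, "port-exists",
                                 f"no send port {gi.source_port!r} on "
                                 f"{src_comp.name!r}"))
            continue
        if rp is None or rp.direction != "receive":
            out.append(Violation(where, "port-exists",
                                 f"no receive port {gi.destination_port!r} on "
                                 f"{dst_comp.name!r}"))
            continue
        if not check_port_compatibility(sp, rp):
            out.append(Violation(
                where, "port-compatibility",
                f"port {gi.source_port!r} ({sp.kind}, "
                f"{sp.dimension.unit_label}) incompatible with "
                f"{gi.destination_port!r} ({rp.kind}, {rp.dimension.unit_label})"))
        _check_scheme(gi.connectivity, src_pop.size, dst_pop.size, where, out)

    return out


def _scheme_count(scheme, n_src: int, n_dst: int) -> int:
    """Number of weight-update instances a scheme will create (>= 1)."""
    if isinstance(scheme, ConnectionList):
        return max(len(scheme), 1)
    if isinstance(scheme, OneToOne):
        return n_src
    if isinstance(scheme, AllToAll):
        return n_src * n_dst
    return max(n_src * n_dst, 1)


def _check_scheme(scheme, n_src: int, n_dst: int, where: str,
                  out: list[Violation]):
    if isinstance(scheme, OneToOne) and n_src != n_dst:
        out.append(Violation(where, "one-to-one-sizes",
                             f"one_to_one between sizes {n_src} and {n_dst}"))
    if isinstance(scheme, ConnectionList):
        for s, d, delay in scheme.triplets:
            if not (0 <= s < n_src and 0 <= d < n_dst):
                out.append(Violation(where, "connection-bounds",
                                     f"connection ({s}, {d}) out of bounds"))
                break
        if any(t[2] < 0 for t in scheme.triplets):
            out.append(Violation(where, "delay-nonnegative",
                                 "negative delay in connection list"))


def _check_property_value(value, n: int, element: str, pname: str,
                          out: list[Violation]):
    if isinstance(value, ValueList):
        indices = [i for i, _ in value.items]
        if len(set(indices)) != len(indices):
            out.append(Violation(element, "value-list-unique",
                                 f"duplicate indices in value list {pname!r}"))
        if any(i < 0 or i >= n for i in indices):
            out.append(Violation(element, "value-list-bounds",
                                 f"value list {pname!r} index out of bounds"))


# ---------------------------------------------------------------------------
# XML: network files
# ---------------------------------------------------------------------------

class NetworkParseError(ValueError):
    pass


def _q(tag: str) -> str:
    return f"{{{ANNOTATION_NS}}}{tag}"


def _fmt(x: float) -> str:
    return repr(float(x))


def _property_element(name: str, value: PropertyValue) -> ET.Element:
    el = ET.Element("Property", {"name": name})
    if isinstance(value, FixedValue):
        ET.SubElement(el, "FixedValue", {"value": _fmt(value.value)})
    elif isinstance(value, ValueList):
        vl = ET.SubElement(el, "ValueList")
        for i, v in value.items:
            ET.SubElement(vl, "Value", {"index": str(i), "value": _fmt(v)})
    elif isinstance(value, UniformDistribution):
        attrs = {"minimum": _fmt(value.minimum), "maximum": _fmt(value.maximum)}
        if value.seed is not None:
            attrs["seed"] = str(value.seed)
        ET.SubElement(el, "UniformDistribution", attrs)
    elif isinstance(value, NormalDistribution):
        attrs = {"mean": _fmt(value.mean), "variance": _fmt(value.variance)}
        if value.seed is not None:
            attrs["seed"] = str(value.seed)
        ET.SubElement(el, "NormalDistribution", attrs)
    else:
        raise TypeError(f"not a property value: {value!r}")
    return el


def _read_property(el: ET.Element) -> tuple[str, PropertyValue]:
    name = el.get("name", "")
    child = next((c for c in el if c.tag != _q("Annotations")), None)
    if child is None:
        raise NetworkParseError(f"property {name!r} has no value")
    if child.tag == "FixedValue":
        return name, FixedValue(float(child.get("value", "0")))
    if child.tag == "ValueList":
        items = tuple(
            (int(v.get("index", "0")), float(v.get("value", "0")))
            for v in child
        )
        return name, ValueList(items)
    if child.tag == "UniformDistribution":
        seed = child.get("seed")
        return name, UniformDistribution(
            float(child.get("minimum", "0")), float(child.get("maximum", "1")),
            int(seed) if seed is not None else None)
    if child.tag == "NormalDistribution":
        seed = child.get("seed")
        return name, NormalDistribution(
            float(child.get("mean", "0")), float(child.get("variance", "0")),
            int(seed) if seed is not None else None)
    raise NetworkParseError(f"unknown tag {child.tag!r}")


def connectivity_element(scheme: ConnectivityScheme) -> ET.Element:
    if isinstance(scheme, OneToOne):
        return ET.Element("OneToOneConnection")
    if isinstance(scheme, AllToAll):
        return ET.Element("AllToAllConnection")
    if isinstance(scheme, FixedProbability):
        attrs = {"probability": _fmt(scheme.p)}
        if scheme.seed is not None:
            attrs["seed"] = str(scheme.seed)
        if scheme.allow_self:
            attrs["allow_self_connections"] = "true"
        return ET.Element("FixedProbabilityConnection", attrs)
    if isinstance(scheme, ConnectionList):
        el = ET.Element("ConnectionList")
        weights = scheme.weights
        for k, (s, d, delay) in enumerate(scheme.triplets):
            attrs = {"src_neuron": str(s), "dst_neuron": str(d),
                     "delay": _fmt(delay)}
            if weights is not None:
                attrs["weight"] = _fmt(weights[k])
            ET.SubElement(el, "Connection", attrs)
        if scheme.recipe is not None:
            from .generators import recipe_annotation  # cycle-free at runtime
            ann = ET.SubElement(el, _q("Annotations"))
            ann.append(recipe_annotation(scheme.recipe))
        return el
    raise TypeError(f"not a connectivity scheme: {scheme!r}")


def read_connectivity(el: ET.Element) -> ConnectivityScheme:
    if el.tag == "OneToOneConnection":
        return OneToOne()
    if el.tag == "AllToAllConnection":
        return AllToAll()
    if el.tag == "FixedProbabilityConnection":
        seed = el.get("seed")
        return FixedProbability(
            float(el.get("probability", "0")),
            int(seed) if seed is not None else None,
            el.get("allow_self_connections", "false") == "true")
    if el.tag == "ConnectionList":
        triplets = []
        weights = []
        has_weight = False
        recipe = None
        for child in el:
            if child.tag == "Connection":
                triplets.append((int(child.get("src_neuron", "0")),
                                 int(child.get("dst_neuron", "0")),
                                 float(child.get("delay", "0"))))
                w = child.get("weight")
                if w is not None:
                    has_weight = True
                    weights.append(float(w))
            elif child.tag == _q("Annotations"):
                from .generators import read_recipe_annotation
                recipe = read_recipe_annotation(child)
            else:
                raise NetworkParseError(f"unknown tag {child.tag!r}")
        return ConnectionList(
            tuple(triplets),
            tuple(weights) if has_weight else None,
            recipe)
    raise NetworkParseError(f"unknown connectivity tag {el.tag!r}")


_CONNECTIVITY_TAGS = (
    "OneToOneConnection", "AllToAllConnection",
    "FixedProbabilityConnection", "ConnectionList",
)


def write_network_xml(net: Network) -> str:
    """Serialise; tool extras (colour, layout_ref, recipes) go inside a
    namespaced Annotations child so plain readers can ignore them."""
    root = ET.Element("SpineMLNetwork", {"name": net.name})
    for pop in net.populations:
        pel = ET.SubElement(root, "Population")
        nel = ET.SubElement(pel, "Neuron", {
            "name": pop.name, "size": str(pop.size),
            "url": f"{pop.component_ref}.xml"})
        for pname, pval in pop.properties:
            nel.append(_property_element(pname, pval))
        if pop.colour is not None or pop.layout_ref is not None:
            ann = ET.SubElement(pel, _q("Annotations"))
            if pop.colour is not None:
                ET.SubElement(ann, _q("Colour")).text = pop.colour
            if pop.layout_ref is not None:
                ET.SubElement(ann, _q("LayoutRef")).text = pop.layout_ref
        for proj in net.projections:
            if proj.source != pop.name:
                continue
            prel = ET.SubElement(pel, "Projection",
                                 {"dst_population": proj.destination})
            for syn in proj.synapses:
                sel = ET.SubElement(prel, "Synapse")
                sel.append(connectivity_element(syn.connectivity))
                wel = ET.SubElement(sel, "WeightUpdate", {
                    "url": f"{syn.weight_update.component_ref}.xml"})
                for pname, pval in syn.weight_update.properties:
                    wel.append(_property_element(pname, pval))
                psel = ET.SubElement(sel, "PostSynapse", {
                    "url": f"{syn.postsynapse.component_ref}.xml"})
                for pname, pval in syn.postsynapse.properties:
                    psel.append(_property_element(pname, pval))
    for gi in net.generic_inputs:
        giel = ET.SubElement(root, "GenericInput", {
            "src_population": gi.source, "src_port": gi.source_port,
            "dst_population": gi.destination, "dst_port": gi.destination_port})
        giel.append(connectivity_element(gi.connectivity))
    ET.indent(root)
    return ET.tostring(root, encoding="unicode")


def _read_binding(el: ET.Element) -> ComponentBinding:
    url = el.get("url", "")
    ref = url[:-4] if url.endswith(".xml") else url
    props = tuple(_read_property(c) for c in el if c.tag == "Property")
    return ComponentBinding(ref, props)


def read_network_xml(text: str) -> Network:
    try:
        root = ET.fromstring(text)
    except ET.ParseError as exc:
        raise NetworkParseError(f"malformed XML: {exc}") from exc
    if root.tag != "SpineMLNetwork":
        raise NetworkParseError(f"unknown root tag {root.tag!r}")
    populations: list[Population] = []
    projections: list[Projection] = []
    generic_inputs: list[GenericInput] = []
    for pel in root:
        if pel.tag == "Population":
            nel = pel.find("Neuron")
            if nel is None:
                raise NetworkParseError("Population without Neuron")
            colour = None
            layout_ref = None
            ann = pel.find(_q("Annotations"))
            if ann is not None:
                cel = ann.find(_q("Colour"))
                colour = cel.text if cel is not None else None
                lel = ann.find(_q("LayoutRef"))
                layout_ref = lel.text if lel is not None else None
            url = nel.get("url", "")
            populations.append(Population(
                name=nel.get("name", ""),
                size=int(nel.get("size", "1")),
                component_ref=url[:-4] if url.endswith(".xml") else url,
                properties=tuple(_read_property(c) for c in nel
                                 if c.tag == "Property"),
                layout_ref=layout_ref,
                colour=colour,
            ))
            for prel in pel:
                if prel.tag != "Projection":
                    continue
                synapses = []
                for sel in prel:
                    if sel.tag != "Synapse":
                        raise NetworkParseError(f"unknown tag {sel.tag!r}")
                    scheme = None
                    wu = ps = None
                    for child in sel:
                        if child.tag in _CONNECTIVITY_TAGS:
                            scheme = read_connectivity(child)
                        elif child.tag == "WeightUpdate":
                            wu = _read_binding(child)
                        elif child.tag == "PostSynapse":
                            ps = _read_binding(child)
                        elif child.tag == _q("Annotations"):
                            pass
                        else:
                            raise NetworkParseError(
                                f"unknown tag {child.tag!r}")
                    if scheme is None or wu is None or ps is None:
                        raise NetworkParseError("incomplete Synapse element")
                    synapses.append(Synapse(scheme, wu, ps))
                projections.append(Projection(
                    populations[-1].name, prel.get("dst_population", ""),
                    tuple(synapses)))
        elif pel.tag == "GenericInput":
            scheme = None
            for child in pel:
                if child.tag in _CONNECTIVITY_TAGS:
                    scheme = read_connectivity(child)
            if scheme is None:
                scheme = OneToOne()
            generic_inputs.append(GenericInput(
                pel.get("src_population", ""), pel.get("src_port", ""),
                pel.get("dst_population", ""), pel.get("dst_port", ""),
                scheme))
        elif pel.tag == _q("Annotations"):
            pass
        else:
            raise NetworkParseError(f"unknown tag {pel.tag!r}")
    return Network(root.get("name", ""), tuple(populations),
                   tuple(projections), tuple(generic_inputs))


# ---------------------------------------------------------------------------
# Project files (a directory of XML files plus a description file)
# ---------------------------------------------------------------------------

class ProjectError(ValueError):
    pass


def write_project(project: Project, directory: str) -> list[str]:
    """Write a project to a working directory; returns the file list."""
    from .experiments import write_experiment_xml
    from .layouts import layout_rule_element

    os.makedirs(directory, exist_ok=True)
    root = ET.Element("Project", {"name": project.name})
    written: list[str] = []

    def emit(kind: str, filename: str, text: str):
        path = os.path.join(directory, filename)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
            if not text.endswith("\n"):
                fh.write("\n")
        ET.SubElement(root, "File", {"type": kind, "path": filename})
        written.append(filename)

    emit("network", f"{project.network.name}.xml",
         write_network_xml(project.network))
    for name in sorted(project.components):
        emit("component", f"{name}.xml",
             write_component_xml(project.components[name]))
    for exp in project.experiments:
        emit("experiment", f"experiment_{exp.name}.xml",
             write_experiment_xml(exp))
    for name in sorted(project.layouts):
        el = layout_rule_element(project.layouts[name])
        ET.indent(el)
        emit("layout", f"layout_{name}.xml",
             ET.tostring(el, encoding="unicode"))

    ET.indent(root)
    path = os.path.join(directory, "project.xml")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(ET.tostring(root, encoding="unicode") + "\n")
    written.append("project.xml")
    return written


def read_project(directory: str) -> Project:
    from .experiments import read_experiment_xml
    from .layouts import read_layout_rule

    path = os.path.join(directory, "project.xml")
    if not os.path.exists(path):
        raise ProjectError(f"no project.xml in {directory!r}")
    root = ET.parse(path).getroot()
    if root.tag != "Project":
        raise ProjectError(f"unknown root tag {root.tag!r}")
    network = None
    components: dict[str, Component] = {}
    experiments = []
    layouts: dict[str, object] = {}
    for fel in root:
        if fel.tag != "File":
            raise ProjectError(f"unknown tag {fel.tag!r}")
        fpath = os.path.join(directory, fel.get("path", ""))
        if not os.path.exists(fpath):
            raise ProjectError(f"listed file missing: {fel.get('path')!r}")
        with open(fpath, encoding="utf-8") as fh:
            text = fh.read()
        kind = fel.get("type", "")
        if kind == "network":
            network = read_network_xml(text)
        elif kind == "component":
            comp = read_component_xml(text)
            components[comp.name] = comp
        elif kind == "experiment":
            experiments.append(read_experiment_xml(text))
        elif kind == "layout":
            rule = read_layout_rule(ET.fromstring(text))
            layouts[rule.name] = rule
        else:
            raise ProjectError(f"unknown file type {kind!r}")
    if network is None:
        raise ProjectError("project lists no network file")
    return Project(root.get("name", ""), network, components, experiments,
                   layouts)
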