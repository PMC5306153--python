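"""Component layer: parameterised hybrid dynamical systems.

A *component* describes one reusable dynamical process — a neuron body, a
weight-update rule, a postsynapse, or a generic process — as a set of
parameters, state variables, aliases (derived quantities), typed ports and
regimes. Each regime holds first-order time derivatives plus transitions
fired by boolean conditions, incoming events, or incoming impulses.

Conventions adopted here (documented in docs/methods.md):

* Time is measured in milliseconds throughout; derivatives are "per ms" and
  the builtin symbol ``t`` (current time, ms) is always in scope.
* An *analog send* port exposes the state variable or alias bearing the same
  name; an *impulse send* port takes its payload from the same-named symbol.
  Those are the only permitted name collisions between ports and symbols.
* ``rand()`` is a layout-engine facility and is rejected inside components.
"""

from __future__ import annotations

import copy
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace

from .expr import ExpressionError, parse_expression

__all__ = [
    "ALLOWED_UNITS",
    "DIMENSIONLESS",
    "Dimension",
    "Parameter",
    "StateVariable",
    "Alias",
    "Port",
    "Transition",
    "Regime",
    "Component",
    "Violation",
    "ComponentValidationError",
    "validate_component",
    "is_valid_component",
    "check_port_compatibility",
    "duplicate_component",
    "read_component_xml",
    "write_component_xml",
]

ALLOWED_UNITS = ("mV", "pA", "nA", "nS", "ms", "s", "Hz", "dimensionless")

_IDENT_RE = re.compile(r"^[A-Za-z][A-Za-z0-9_]*$")

#: Symbols bound by the runtime, always legal in component expressions.
BUILTIN_SYMBOLS = frozenset({"t"})


@dataclass(frozen=True)
class Dimension:
    """A unit label; equality of labels is the whole unit system."""

    unit_label: str = "dimensionless"

    def __post_init__(self):
        if self.unit_label not in ALLOWED_UNITS:
            raise ValueError(
                f"unknown unit label {self.unit_label!r}; "
                f"allowed: {', '.join(ALLOWED_UNITS)}"
            )


DIMENSIONLESS = Dimension()


@dataclass(frozen=True)
class Parameter:
    name: str
    dimension: Dimension = DIMENSIONLESS


@dataclass(frozen=True)
class StateVariable:
    name: str
    dimension: Dimension = DIMENSIONLESS


@dataclass(frozen=True)
class Alias:
    """A named derived quantity, e.g. the clipped output of a rate unit."""

    name: str
    expression: str


@dataclass(frozen=True)
class Port:
    """Typed communication endpoint.

    kind ``analog`` carries a continuous value, ``event`` a bare spike,
    ``impulse`` a spike with a payload value. ``reduce_rule='sum'`` is only
    meaningful for analog receive ports and sums over all wired senders.
    """

    name: str
    direction: str  # send | receive
    kind: str  # analog | event | impulse
    dimension: Dimension = DIMENSIONLESS
    reduce_rule: str = "none"  # none | sum


@dataclass(frozen=True)
class Transition:
    """A regime transition.

    ``trigger`` is a boolean expression for condition transitions, or the
    name of the receiving event/impulse port for event/impulse transitions.
    For impulse transitions the port name is bound to the payload inside the
    assignment expressions.
    """

    trigger: str
    target_regime: str
    assignments: tuple[tuple[str, str], ...] = ()
    emits: tuple[str, ...] = ()


@dataclass(frozen=True)
class Regime:
    name: str
    time_derivatives: tuple[tuple[str, str], ...] = ()
    on_conditions: tuple[Transition, ...] = ()
    on_events: tuple[Transition, ...] = ()
    on_impulses: tuple[Transition, ...] = ()


@dataclass(frozen=True)
class Component:
    name: str
    kind: str  # neuron_body | weight_update | postsynapse | generic
    parameters: tuple[Parameter, ...] = ()
    state_variables: tuple[StateVariable, ...] = ()
    aliases: tuple[Alias, ...] = ()
    ports: tuple[Port, ...] = ()
    regimes: tuple[Regime, ...] = ()
    initial_regime: str = ""

    def __post_init__(self):
        if not self.initial_regime and self.regimes:
            object.__setattr__(self, "initial_regime", self.regimes[0].name)

    # -- symbol lookups ----------------------------------------------------
    def parameter_names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.parameters)

    def state_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.state_variables)

    def alias_names(self) -> tuple[str, ...]:
        return tuple(a.name for a in self.aliases)

    def receive_ports(self) -> tuple[Port, ...]:
        return tuple(p for p in self.ports if p.direction == "receive")

    def send_ports(self) -> tuple[Port, ...]:
        return tuple(p for p in self.ports if p.direction == "send")

    def port(self, name: str) -> Port | None:
        for p in self.ports:
            if p.name == name:
                return p
        return None

    def regime(self, name: str) -> Regime | None:
        for r in self.regimes:
            if r.name == name:
                return r
        return None

    def property_names(self) -> tuple[str, ...]:
        """Names configurable from the network layer."""
        return self.parameter_names() + self.state_names()


@dataclass(frozen=True)
class Violation:
    element: str
    rule: str
    message: str
    severity: str = "error"  # error | warning

    def __str__(self):
        return f"[{self.severity}] {self.element}: {self.message} ({self.rule})"


class ComponentValidationError(ValueError):
    def __init__(self, violations: list[Violation]):
        super().__init__(
            "invalid component:\n" + "\n".join(str(v) for v in violations)
        )
        self.violations = violations


def _check_expr(
    text: str,
    allowed: set[str],
    element: str,
    rule: str,
    out: list[Violation],
):
    try:
        expr = parse_expression(text)
    except ExpressionError as exc:
        out.append(Violation(element, rule, f"cannot parse {text!r}: {exc}"))
        return
    if expr.uses_rand:
        out.append(
            Violation(
                element, "no-rand-in-components",
                "rand() is a layout-engine facility, not allowed here",
            )
        )
    for name in sorted(expr.variables - allowed - BUILTIN_SYMBOLS):
        out.append(
            Violation(element, rule, f"unresolved symbol {name!r} in {text!r}")
        )


def _alias_order(component: Component) -> list[Alias] | None:
    """Topological order of aliases, or None on a reference cycle."""
    names = {a.name: a for a in component.aliases}
    order: list[Alias] = []
    state: dict[str, int] = {}

    def visit(name: str) -> bool:
        if state.get(name) == 2:
            return True
        if state.get(name) == 1:
            return False
        state[name] = 1
        try:
            deps = parse_expression(names[name].expression).variables
        except ExpressionError:
            deps = frozenset()
        for dep in deps:
            if dep in names and not visit(dep):
                return False
        state[name] = 2
        order.append(names[name])
        return True

    for alias in component.aliases:
        if not visit(alias.name):
            return None
    return order


def validate_component(component: Component) -> list[Violation]:
    """Check every structural invariant; returns violations, raises nothing.

    A component is usable by the simulator iff no error-severity violation
    is returned. A component with zero state variables (a pure relay) is
    legal but flagged with a warning.
    """
    out: list[Violation] = []
    c = component

    if c.kind not in ("neuron_body", "weight_update", "postsynapse", "generic"):
        out.append(Violation(c.name, "component-kind", f"unknown kind {c.kind!r}"))
    if not _IDENT_RE.match(c.name or ""):
        out.append(Violation(c.name, "identifier", f"bad component name {c.name!r}"))

    # Symbol namespace: parameters, state variables, aliases, receive ports
    # share one namespace. Send ports may only collide as value sources.
    symbols: dict[str, str] = {}
    value_sources = set(c.state_names()) | set(c.alias_names())
    payload_sources = value_sources | set(c.parameter_names())

    def declare(name: str, what: str):
        if not _IDENT_RE.match(name or ""):
            out.append(Violation(name, "identifier", f"bad identifier {name!r}"))
        if name in symbols:
            out.append(
                Violation(
                    name, "unique-symbol",
                    f"{what} {name!r} collides with {symbols[name]}",
                )
            )
        else:
            symbols[name] = what

    for p in c.parameters:
        declare(p.name, "parameter")
    for s in c.state_variables:
        declare(s.name, "state variable")
    for a in c.aliases:
        declare(a.name, "alias")

    for port in c.ports:
        if port.direction not in ("send", "receive"):
            out.append(Violation(port.name, "port-direction",
                                 f"bad direction {port.direction!r}"))
            continue
        if port.kind not in ("analog", "event", "impulse"):
            out.append(Violation(port.name, "port-kind",
                                 f"bad kind {port.kind!r}"))
            continue
        if port.kind == "event" and port.dimension != DIMENSIONLESS:
            out.append(Violation(port.name, "event-port-dimensionless",
                                 "event ports are dimensionless"))
        if port.reduce_rule == "sum" and not (
            port.kind == "analog" and port.direction == "receive"
        ):
            out.append(Violation(port.name, "reduce-analog-receive-only",
                                 "reduce_rule='sum' requires an analog receive port"))
        if port.reduce_rule not in ("none", "sum"):
            out.append(Violation(port.name, "reduce-rule",
                                 f"bad reduce_rule {port.reduce_rule!r}"))
        if port.direction == "receive":
            declare(port.name, "receive port")
        else:
            # Send ports: analog must expose a same-named state/alias,
            # impulse a same-named parameter/state/alias; event must be fresh.
            if port.kind == "analog" and port.name not in value_sources:
                out.append(Violation(
                    port.name, "analog-send-source",
                    "analog send port must share its name with a state "
                    "variable or alias providing its value"))
            if port.kind == "impulse" and port.name not in payload_sources:
                out.append(Violation(
                    port.name, "impulse-send-payload",
                    "impulse send port must share its name with the symbol "
                    "providing its payload"))
            if port.kind == "event" and port.name in symbols:
                out.append(Violation(
                    port.name, "unique-symbol",
                    f"event send port {port.name!r} collides with "
                    f"{symbols[port.name]}"))

    seen_ports: set[str] = set()
    for port in c.ports:
        key = port.name
        if key in seen_ports:
            out.append(Violation(port.name, "unique-port",
                                 f"duplicate port name {port.name!r}"))
        seen_ports.add(key)

    readable = (
        set(c.parameter_names()) | set(c.state_names()) | set(c.alias_names())
        | {p.name for p in c.receive_ports() if p.kind == "analog"}
    )

    if _alias_order(c) is None:
        out.append(Violation(c.name, "alias-cycle",
                             "alias definitions form a reference cycle"))
    for a in c.aliases:
        _check_expr(a.expression, readable - {a.name}, f"alias {a.name}",
                    "alias-symbols", out)
        # self-reference caught by cycle check; exclude to avoid duplicates

    if not c.regimes:
        out.append(Violation(c.name, "at-least-one-regime",
                             "component has no regimes"))
    regime_names = [r.name for r in c.regimes]
    if len(set(regime_names)) != len(regime_names):
        out.append(Violation(c.name, "unique-regime", "duplicate regime names"))
    if c.regimes and c.initial_regime not in regime_names:
        out.append(Violation(c.initial_regime, "initial-regime-exists",
                             f"initial regime {c.initial_regime!r} not defined"))

    state_set = set(c.state_names())
    event_in = {p.name for p in c.receive_ports() if p.kind == "event"}
    impulse_in = {p.name for p in c.receive_ports() if p.kind == "impulse"}
    send_names = {p.name for p in c.send_ports()}

    for r in c.regimes:
        seen_td: set[str] = set()
        for var, expr_text in r.time_derivatives:
            if var not in state_set:
                out.append(Violation(f"{r.name}/{var}", "derivative-of-state",
                                     f"derivative of undeclared state {var!r}"))
            if var in seen_td:
                out.append(Violation(f"{r.name}/{var}", "one-derivative-per-state",
                                     f"state {var!r} has two derivatives"))
            seen_td.add(var)
            _check_expr(expr_text, readable, f"{r.name}/d{var}/dt",
                        "derivative-symbols", out)

        def check_transition(tr: Transition, flavour: str):
            where = f"{r.name}/{flavour}"
            if tr.target_regime not in regime_names:
                out.append(Violation(where, "transition-target",
                                     f"unknown target regime {tr.target_regime!r}"))
            extra: set[str] = set()
            if flavour == "on_condition":
                _check_expr(tr.trigger, readable, where, "trigger-symbols", out)
            elif flavour == "on_event":
                if tr.trigger not in event_in:
                    out.append(Violation(where, "trigger-port",
                                         f"{tr.trigger!r} is not an event receive port"))
            else:
                if tr.trigger not in impulse_in:
                    out.append(Violation(where, "trigger-port",
                                         f"{tr.trigger!r} is not an impulse receive port"))
                extra = {tr.trigger}  # payload bound under the port name
            for var, expr_text in tr.assignments:
                if var not in state_set:
                    out.append(Violation(where, "assign-to-state",
                                         f"assignment to undeclared state {var!r}"))
                _check_expr(expr_text, readable | extra, f"{where}/{var}",
                            "assignment-symbols", out)
            for emitted in tr.emits:
                if emitted not in send_names:
                    out.append(Violation(where, "emit-send-port",
                                         f"{emitted!r} is not a send port"))

        for tr in r.on_conditions:
            check_transition(tr, "on_condition")
        for tr in r.on_events:
            check_transition(tr, "on_event")
        for tr in r.on_impulses:
            check_transition(tr, "on_impulse")

    if not c.state_variables:
        out.append(Violation(c.name, "stateless-component",
                             "component has no state variables (pure relay)",
                             severity="warning"))
    return out


def is_valid_component(component: Component) -> bool:
    return not any(v.severity == "error" for v in validate_component(component))


def check_port_compatibility(send: Port, receive: Port) -> bool:
    """True iff the two ports may be wired: same kind and same dimension."""
    if send.direction != "send" or receive.direction != "receive":
        raise ValueError(
            "check_port_compatibility expects (send, receive) ports, got "
            f"({send.direction}, {receive.direction})"
        )
    return send.kind == receive.kind and send.dimension == receive.dimension


def duplicate_component(
    component: Component,
    new_name: str,
    existing_names: set[str] | frozenset[str] = frozenset(),
) -> Component:
    """Deep-copy a component under a new name; the source is untouched."""
    if new_name == component.name or new_name in existing_names:
        raise ValueError(f"component name {new_name!r} already in use")
    return replace(copy.deepcopy(component), name=new_name)


# ---------------------------------------------------------------------------
# XML dialect
# ---------------------------------------------------------------------------

_PORT_TAGS = {
    ("send", "analog", "none"): "AnalogSendPort",
    ("receive", "analog", "none"): "AnalogReceivePort",
    ("receive", "analog", "sum"): "AnalogReducePort",
    ("send", "event", "none"): "EventSendPort",
    ("receive", "event", "none"): "EventReceivePort",
    ("send", "impulse", "none"): "ImpulseSendPort",
    ("receive", "impulse", "none"): "ImpulseReceivePort",
}
_TAG_PORTS = {v: k for k, v in _PORT_TAGS.items()}


class ComponentParseError(ValueError):
    pass


def _dim_attrs(dim: Dimension) -> dict:
    return {} if dim == DIMENSIONLESS else {"dimension": dim.unit_label}


def _read_dim(el: ET.Element) -> Dimension:
    label = el.get("dimension", "dimensionless")
    try:
        return Dimension(label)
    except ValueError as exc:
        raise ComponentParseError(str(exc)) from exc


def _math_inline(parent: ET.Element, text: str):
    m = ET.SubElement(parent, "MathInline")
    m.text = text


def _get_math(el: ET.Element, what: str) -> str:
    m = el.find("MathInline")
    if m is None or not (m.text or "").strip():
        raise ComponentParseError(f"missing MathInline in {what}")
    return m.text.strip()


def write_component_xml(component: Component) -> str:
    """Serialise a component to its XML dialect (one component per file)."""
    root = ET.Element(
        "ComponentClass", {"name": component.name, "type": component.kind}
    )
    for p in component.parameters:
        ET.SubElement(root, "Parameter", {"name": p.name, **_dim_attrs(p.dimension)})
    for s in component.state_variables:
        ET.SubElement(root, "StateVariable",
                      {"name": s.name, **_dim_attrs(s.dimension)})
    for a in component.aliases:
        el = ET.SubElement(root, "Alias", {"name": a.name})
        _math_inline(el, a.expression)
    for port in component.ports:
        tag = _PORT_TAGS[(port.direction, port.kind, port.reduce_rule)]
        ET.SubElement(root, tag, {"name": port.name, **_dim_attrs(port.dimension)})
    for r in component.regimes:
        rel = ET.SubElement(root, "Regime", {"name": r.name})
        for var, expr_text in r.time_derivatives:
            tdel = ET.SubElement(rel, "TimeDerivative", {"variable": var})
            _math_inline(tdel, expr_text)

        def write_transition(tr: Transition, tag: str, parent=rel):
            attrs = {"target_regime": tr.target_regime}
            if tag != "OnCondition":
                attrs["src_port"] = tr.trigger
            tel = ET.SubElement(parent, tag, attrs)
            if tag == "OnCondition":
                trig = ET.SubElement(tel, "Trigger")
                _math_inline(trig, tr.trigger)
            for var, expr_text in tr.assignments:
                ael = ET.SubElement(tel, "StateAssignment", {"variable": var})
                _math_inline(ael, expr_text)
            for emitted in tr.emits:
                port = component.port(emitted)
                out_tag = "ImpulseOut" if port and port.kind == "impulse" else "EventOut"
                ET.SubElement(tel, out_tag, {"port": emitted})

        for tr in r.on_conditions:
            write_transition(tr, "OnCondition")
        for tr in r.on_events:
            write_transition(tr, "OnEvent")
        for tr in r.on_impulses:
            write_transition(tr, "OnImpulse")
    if component.regimes and component.initial_regime != component.regimes[0].name:
        root.set("initial_regime", component.initial_regime)
    ET.indent(root)
    return ET.tostring(root, encoding="unicode", xml_declaration=False)


def read_component_xml(text: str, validate: bool = True) -> Component:
    """Parse component XML; raises ComponentValidationError on invariant
    violations unless ``validate=False``."""
    try:
        root = ET.fromstring(text)
    except ET.ParseError as exc:
        raise ComponentParseError(f"malformed XML: {exc}") from exc
    if root.tag != "ComponentClass":
        raise ComponentParseError(f"unknown root tag {root.tag!r}")

    parameters: list[Parameter] = []
    states: list[StateVariable] = []
    aliases: list[Alias] = []
    ports: list[Port] = []
    regimes: list[Regime] = []

    def read_transition(el: ET.Element, flavour: str) -> Transition:
        target = el.get("target_regime", "")
        if flavour == "OnCondition":
            trig_el = el.find("Trigger")
            if trig_el is None:
                raise ComponentParseError("OnCondition without Trigger")
            trigger = _get_math(trig_el, "Trigger")
        else:
            trigger = el.get("src_port", "")
        assignments = []
        emits = []
        for child in el:
            if child.tag == "StateAssignment":
                assignments.append(
                    (child.get("variable", ""), _get_math(child, "StateAssignment"))
                )
            elif child.tag in ("EventOut", "ImpulseOut"):
                emits.append(child.get("port", ""))
            elif child.tag in ("Trigger",):
                pass
            else:
                raise ComponentParseError(f"unknown tag {child.tag!r}")
        return Transition(trigger, target, tuple(assignments), tuple(emits))

    for el in root:
        if el.tag == "Parameter":
            parameters.append(Parameter(el.get("name", ""), _read_dim(el)))
        elif el.tag == "StateVariable":
            states.append(StateVariable(el.get("name", ""), _read_dim(el)))
        elif el.tag == "Alias":
            aliases.append(Alias(el.get("name", ""), _get_math(el, "Alias")))
        elif el.tag in _TAG_PORTS:
            direction, kind, reduce_rule = _TAG_PORTS[el.tag]
            ports.append(Port(el.get("name", ""), direction, kind,
                              _read_dim(el), reduce_rule))
        elif el.tag == "Regime":
            tds = []
            on_conditions, on_events, on_impulses = [], [], []
            for child in el:
                if child.tag == "TimeDerivative":
                    tds.append((child.get("variable", ""),
                                _get_math(child, "TimeDerivative")))
                elif child.tag == "OnCondition":
                    on_conditions.append(read_transition(child, "OnCondition"))
                elif child.tag == "OnEvent":
                    on_events.append(read_transition(child, "OnEvent"))
                elif child.tag == "OnImpulse":
                    on_impulses.append(read_transition(child, "OnImpulse"))
                else:
                    raise ComponentParseError(f"unknown tag {child.tag!r}")
            regimes.append(Regime(el.get("name", ""), tuple(tds),
                                  tuple(on_conditions), tuple(on_events),
                                  tuple(on_impulses)))
        elif el.tag == "Annotations":
            pass  # foreign-tool annotations are skipped
        else:
            raise ComponentParseError(f"unknown tag {el.tag!r}")

    component = Component(
        name=root.get("name", ""),
        kind=root.get("type", "generic"),
        parameters=tuple(parameters),
        state_variables=tuple(states),
        aliases=tuple(aliases),
        ports=tuple(ports),
        regimes=tuple(regimes),
        initial_regime=root.get(
            "initial_regime", regimes[0].name if regimes else ""
        ),
    )
    if validate:
        violations = [v for v in validate_component(component)
                      if v.severity == "error"]
        if violations:
            raise ComponentValidationError(violations)
    return component
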