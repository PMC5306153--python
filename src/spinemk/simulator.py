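"""Fixed-step reference simulator.

The runtime flattens a resolved project + experiment into per-population
NumPy state arrays (one *group* per population, plus one group of
weight-update instances per connection and one group of postsynapse
instances per target neuron for every synapse), integrates all time
derivatives with forward Euler, fires condition transitions on false→true
edges, and routes events/impulses through a step-indexed delay queue.

Update order within a step (synchronous/Jacobi between populations):

1. analog send values are read from previous-step state everywhere;
2. they propagate through the weight-update and postsynapse stages of every
   synapse and through generic inputs, summing on reduce ports;
3. experiment analog inputs are added;
4. all groups take one forward-Euler step;
5. condition transitions fire on false→true edges (ties by declaration
   order), apply their assignments, switch regimes and emit;
6. emitted events/impulses are enqueued with their connection delays
   (rounded to steps, minimum one step for spike legs; impulse transfer
   from a weight-update to its own postsynapse is immediate);
7. queue items due this step are delivered, firing on_event/on_impulse
   transitions;
8. loggers sample.

Time is milliseconds internally; experiment durations (s) are converted.
All randomness flows from a single master seed via stable path hashing, so
identical (project, experiment, seed) gives bit-identical logs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .expr import additive_increment, parse_expression
from .experiments import (
    ConstantInput,
    Experiment,
    Logger,
    RegularSpikeInput,
    TimeVaryingInput,
    apply_property_changes,
    input_value,
    spike_times,
    write_log_metadata,
)
from .generators import needs_regeneration, regenerate
from .layouts import generate_layout
from .model_core import Component, check_port_compatibility, _alias_order
from .network import (
    ConnectionList,
    Network,
    Project,
    derive_seed,
    instantiate_connectivity,
    sample_property,
    validate_network,
)

__all__ = [
    "SimulationError",
    "WiringError",
    "AnalogTrace",
    "EventTrace",
    "LogSet",
    "RuntimeModel",
    "build_runtime",
    "run",
    "run_external_simulator",
    "ComponentBench",
]


class SimulationError(RuntimeError):
    pass


class WiringError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Compiled components and instance groups
# ---------------------------------------------------------------------------

class _CompiledComponent:
    """Expression tables for one component, compiled once."""

    def __init__(self, comp: Component):
        self.comp = comp
        order = _alias_order(comp)
        if order is None:
            raise SimulationError(f"component {comp.name!r} has alias cycle")
        self.aliases = [(a.name, parse_expression(a.expression)) for a in order]
        self.regime_names = [r.name for r in comp.regimes]
        self.regime_index = {n: i for i, n in enumerate(self.regime_names)}
        self.derivatives = []  # per regime: list of (var, expr)
        self.conditions = []  # per regime: list of (expr, transition)
        self.on_events = []  # per regime: dict port -> list of transitions
        self.on_impulses = []  # per regime: dict port -> list of transitions
        for r in comp.regimes:
            self.derivatives.append(
                [(var, parse_expression(text))
                 for var, text in r.time_derivatives])
            self.conditions.append(
                [(parse_expression(tr.trigger), tr) for tr in r.on_conditions])
            ev: dict[str, list] = {}
            for tr in r.on_events:
                ev.setdefault(tr.trigger, []).append(tr)
            self.on_events.append(ev)
            im: dict[str, list] = {}
            for tr in r.on_impulses:
                im.setdefault(tr.trigger, []).append(tr)
            self.on_impulses.append(im)
        self.n_conditions = sum(len(c) for c in self.conditions)


class _Group:
    """A vector of instances of one component (a population, or the
    weight-update/postsynapse instances of one synapse)."""

    def __init__(self, label: str, comp: Component, n: int,
                 properties: dict[str, np.ndarray]):
        self.label = label
        self.comp = comp
        self.compiled = _CompiledComponent(comp)
        self.n = n
        self.params: dict[str, np.ndarray] = {}
        self.states: dict[str, np.ndarray] = {}
        for p in comp.parameters:
            self.params[p.name] = properties.get(p.name, np.zeros(n)).copy()
        for s in comp.state_variables:
            self.states[s.name] = properties.get(s.name, np.zeros(n)).copy()
        self.regime = np.full(
            n, self.compiled.regime_index.get(comp.initial_regime, 0),
            dtype=np.int64)
        self.port_in: dict[str, np.ndarray] = {
            p.name: np.zeros(n)
            for p in comp.receive_ports() if p.kind == "analog"}
        # previous truth per condition, keyed (regime_idx, cond_idx)
        self.cond_prev: dict[tuple[int, int], np.ndarray] = {}
        for ri, conds in enumerate(self.compiled.conditions):
            for ci in range(len(conds)):
                self.cond_prev[(ri, ci)] = np.zeros(n, dtype=bool)
        # event emissions this step: port -> index array (with multiplicity)
        self.emitted: dict[str, list[np.ndarray]] = {}

    def env(self, t: float, port_in: dict[str, np.ndarray] | None = None):
        e: dict[str, object] = {"t": t}
        e.update(self.params)
        e.update(self.states)
        e.update(port_in if port_in is not None else self.port_in)
        for name, expr in self.compiled.aliases:
            e[name] = np.broadcast_to(
                np.asarray(expr(e), dtype=np.float64), (self.n,))
        return e

    def send_value(self, port_name: str, env: dict) -> np.ndarray:
        value = env.get(port_name)
        if value is None:
            raise SimulationError(
                f"{self.label}: no value source for send port {port_name!r}")
        return np.broadcast_to(np.asarray(value, dtype=np.float64), (self.n,))

    def euler_step(self, dt: float, t_next: float, step: int):
        env = self.env(t_next)
        multi = len(self.compiled.regime_names) > 1
        updates: list[tuple[str, np.ndarray, np.ndarray | None]] = []
        for ri, derivs in enumerate(self.compiled.derivatives):
            if not derivs:
                continue
            mask = (self.regime == ri) if multi else None
            for var, expr in derivs:
                dx = np.asarray(expr(env), dtype=np.float64)
                updates.append((var, np.broadcast_to(dx, (self.n,)), mask))
        for var, dx, mask in updates:
            if mask is None:
                self.states[var] = self.states[var] + dt * dx
            else:
                out = self.states[var].copy()
                out[mask] += dt * dx[mask]
                self.states[var] = out
        for var, arr in self.states.items():
            if not np.all(np.isfinite(arr)):
                bad = int(np.flatnonzero(~np.isfinite(arr))[0])
                raise SimulationError(
                    f"non-finite state: {self.label} neuron {bad} "
                    f"variable {var!r} at step {step}")

    def fire_conditions(self, t: float) -> None:
        """Fire condition transitions on false→true edges; record emissions
        in self.emitted."""
        env = self.env(t)
        for ri, conds in enumerate(self.compiled.conditions):
            if not conds:
                continue
            for ci, (trigger, tr) in enumerate(conds):
                in_regime = self.regime == ri  # earlier ties may have switched
                if not in_regime.any():
                    continue
                truth = np.asarray(trigger(env), dtype=np.float64) != 0
                truth = np.broadcast_to(truth, (self.n,))
                fire = in_regime & truth & ~self.cond_prev[(ri, ci)]
                if not fire.any():
                    continue
                idx = np.flatnonzero(fire)
                self._apply_transition(tr, idx, env, t)
                env = self.env(t)  # assignments may feed later conditions

    def _apply_transition(self, tr, idx: np.ndarray, env: dict, t: float,
                          payload: np.ndarray | None = None,
                          payload_port: str | None = None):
        if payload is not None and payload_port is not None:
            env = dict(env)
            env[payload_port] = np.zeros(self.n)
        new_values = []
        for var, text in tr.assignments:
            expr = parse_expression(text)
            if payload is not None and payload_port in expr.variables:
                inc = additive_increment(text, var)
                if inc is not None:
                    # scatter-add so simultaneous impulses on one target sum
                    local = {k: (v[idx] if isinstance(v, np.ndarray) else v)
                             for k, v in env.items()}
                    local[payload_port] = payload
                    vals = np.broadcast_to(
                        np.asarray(inc(local), dtype=np.float64),
                        (len(idx),))
                    new_values.append((var, "add", vals))
                    continue
                local = {k: (v[idx] if isinstance(v, np.ndarray) else v)
                         for k, v in env.items()}
                local[payload_port] = payload
                vals = np.broadcast_to(
                    np.asarray(expr(local), dtype=np.float64), (len(idx),))
                new_values.append((var, "set_last", vals))
                continue
            vals = np.broadcast_to(
                np.asarray(expr(env), dtype=np.float64), (self.n,))[idx] \
                if payload is None else np.broadcast_to(
                    np.asarray(expr({k: (v[idx] if isinstance(v, np.ndarray)
                                         else v) for k, v in env.items()}),
                               dtype=np.float64), (len(idx),))
            new_values.append((var, "set", vals))
        for var, mode, vals in new_values:
            if mode == "add":
                np.add.at(self.states[var], idx, vals)
            else:
                # duplicate indices: last occurrence wins (FIFO within step)
                self.states[var][idx] = vals
        target = self.compiled.regime_index[tr.target_regime]
        self.regime[idx] = target
        for port in tr.emits:
            self.emitted.setdefault(port, []).append(idx.copy())

    def deliver(self, flavour: str, port: str, idx: np.ndarray,
                payload: np.ndarray | None, t: float):
        """Deliver events ('event') or impulses ('impulse') to instances."""
        env = self.env(t)
        table = (self.compiled.on_events if flavour == "event"
                 else self.compiled.on_impulses)
        for ri in range(len(self.compiled.regime_names)):
            transitions = table[ri].get(port)
            if not transitions:
                continue
            sel = self.regime[idx] == ri
            if not sel.any():
                continue
            sub_idx = idx[sel]
            sub_payload = payload[sel] if payload is not None else None
            for tr in transitions:
                self._apply_transition(
                    tr, sub_idx, env, t,
                    payload=sub_payload, payload_port=port if flavour ==
                    "impulse" else None)

    def refresh_condition_memory(self, t: float):
        env = self.env(t)
        for ri, conds in enumerate(self.compiled.conditions):
            for ci, (trigger, _tr) in enumerate(conds):
                truth = np.asarray(trigger(env), dtype=np.float64) != 0
                self.cond_prev[(ri, ci)] = np.broadcast_to(
                    truth, (self.n,)).copy()

    def take_emissions(self) -> dict[str, np.ndarray]:
        out = {}
        for port, chunks in self.emitted.items():
            if chunks:
                out[port] = np.concatenate(chunks)
        self.emitted = {}
        return out

    def value_of(self, name: str, t: float) -> np.ndarray:
        env = self.env(t)
        if name in env:
            return np.broadcast_to(
                np.asarray(env[name], dtype=np.float64), (self.n,))
        raise SimulationError(
            f"{self.label}: no loggable quantity {name!r}")


# ---------------------------------------------------------------------------
# Wiring
# ---------------------------------------------------------------------------

def _first_compatible(send_ports, receive_ports, where: str,
                      kinds: tuple[str, ...]):
    for sp in send_ports:
        if sp.kind not in kinds:
            continue
        for rp in receive_ports:
            if rp.kind in kinds and check_port_compatibility(sp, rp):
                return sp, rp
    raise WiringError(
        f"{where}: no compatible ({'/'.join(kinds)}) send/receive port pair")


@dataclass
class _SynapseRuntime:
    label: str
    src_pop: str
    dst_pop: str
    conn_src: np.ndarray
    conn_dst: np.ndarray
    delay_steps: np.ndarray
    wu: _Group  # one instance per connection
    ps: _Group  # one instance per destination neuron
    src_port: str
    wu_in_port: str
    wu_out_port: str
    ps_in_port: str
    ps_out_port: str
    neuron_in_port: str
    mode: str  # "analog" | "event"


@dataclass
class _GenericInputRuntime:
    label: str
    src_pop: str
    dst_pop: str
    src_port: str
    dst_port: str
    conn_src: np.ndarray
    conn_dst: np.ndarray
    delay_steps: np.ndarray
    mode: str  # "analog" | "event"


@dataclass
class AnalogTrace:
    times: np.ndarray  # seconds
    indices: tuple[int, ...]
    data: np.ndarray  # (n_rows, n_indices)


@dataclass
class EventTrace:
    times: np.ndarray  # seconds
    indices: np.ndarray


@dataclass
class LogSet:
    analog: dict[str, AnalogTrace] = field(default_factory=dict)
    events: dict[str, EventTrace] = field(default_factory=dict)
    dt: float = 0.1  # ms
    loggers: dict[str, Logger] = field(default_factory=dict)

    def write(self, out_dir: str) -> list[str]:
        """One data file plus one XML descriptor per logger."""
        os.makedirs(out_dir, exist_ok=True)
        written = []
        for name, trace in self.analog.items():
            data_file = f"{name}.bin"
            trace.data.astype("<f8").tofile(os.path.join(out_dir, data_file))
            meta = write_log_metadata(
                self.loggers[name], trace.data.shape[0], self.dt, data_file,
                trace.data.shape[1])
            with open(os.path.join(out_dir, f"{name}_log.xml"), "w",
                      encoding="utf-8") as fh:
                fh.write(meta + "\n")
            written += [data_file, f"{name}_log.xml"]
        for name, trace in self.events.items():
            data_file = f"{name}.csv"
            with open(os.path.join(out_dir, data_file), "w",
                      encoding="utf-8") as fh:
                fh.write("time,index\n")
                for t, i in zip(trace.times, trace.indices):
                    fh.write(f"{t!r},{int(i)}\n")
            meta = write_log_metadata(
                self.loggers[name], len(trace.times), self.dt, data_file)
            with open(os.path.join(out_dir, f"{name}_log.xml"), "w",
                      encoding="utf-8") as fh:
                fh.write(meta + "\n")
            written += [data_file, f"{name}_log.xml"]
        return written


@dataclass
class RuntimeModel:
    populations: dict[str, _Group]
    synapses: list[_SynapseRuntime]
    generic_inputs: list[_GenericInputRuntime]
    experiment: Experiment
    dt: float  # ms
    n_steps: int
    master_seed: int
    # schedule: step -> list of queue items
    queue: dict[int, list] = field(default_factory=dict)
    analog_inputs: list = field(default_factory=list)
    spike_schedule: dict[int, list] = field(default_factory=dict)


def _quantise_delay(delay_ms: np.ndarray, dt: float, event: bool) -> np.ndarray:
    steps = np.rint(np.asarray(delay_ms, dtype=np.float64) / dt).astype(np.int64)
    if event:
        steps = np.maximum(steps, 1)
    elif (steps != 0).any():
        raise WiringError("analog connections support delay 0 only")
    return steps


def _sample_binding_properties(comp: Component, properties, n: int,
                               master_seed: int, *path) -> dict:
    out = {}
    for pname, pval in properties:
        out[pname] = sample_property(
            pval, n, derive_seed(master_seed, "prop", *path, pname))
    return out


def _coordinates_for(project: Project, pop_name: str):
    pop = project.network.population(pop_name)
    if pop is None or pop.layout_ref is None:
        return None
    rule = project.layouts.get(pop.layout_ref)
    if rule is None:
        return None
    return generate_layout(rule, pop.size)


def build_runtime(project: Project, experiment: Experiment | str,
                  master_seed: int = 0) -> RuntimeModel:
    """Flatten a project + experiment into arrays ready to step."""
    if isinstance(experiment, str):
        matches = [e for e in project.experiments if e.name == experiment]
        if not matches:
            raise ValueError(f"no experiment named {experiment!r}")
        experiment = matches[0]

    violations = [v for v in validate_network(project.network,
                                              project.components)
                  if v.severity == "error"]
    if violations:
        raise SimulationError(
            "network does not validate:\n"
            + "\n".join(str(v) for v in violations))

    net = apply_property_changes(project.network, experiment)
    dt = experiment.dt
    n_steps = experiment.n_steps()

    groups: dict[str, _Group] = {}
    for pop in net.populations:
        comp = project.components[pop.component_ref]
        props = _sample_binding_properties(
            comp, pop.properties, pop.size, master_seed, pop.name)
        groups[pop.name] = _Group(pop.name, comp, pop.size, props)

    sizes = {p.name: p.size for p in net.populations}
    synapses: list[_SynapseRuntime] = []
    for pi, proj in enumerate(net.projections):
        n_src, n_dst = sizes[proj.source], sizes[proj.destination]
        for si, syn in enumerate(proj.synapses):
            label = f"{proj.source}->{proj.destination}[{si}]"
            scheme = syn.connectivity
            if isinstance(scheme, ConnectionList) and scheme.recipe is not None:
                recipe = scheme.recipe
                if needs_regeneration(recipe, recipe.source_text,
                                      recipe.values, n_src, n_dst):
                    src_xyz = _coordinates_for(project, proj.source)
                    dst_xyz = _coordinates_for(project, proj.destination)
                    if src_xyz is None or dst_xyz is None:
                        raise SimulationError(
                            f"{label}: connection recipe is stale and no "
                            "layouts are available to regenerate it")
                    from dataclasses import replace as _replace
                    recipe = _replace(recipe, n_src=n_src, n_dst=n_dst)
                    scheme = regenerate(recipe, src_xyz, dst_xyz)
            clist = instantiate_connectivity(
                scheme, n_src, n_dst,
                seed=derive_seed(master_seed, "conn", proj.source,
                                 proj.destination, si),
                same_population=proj.source == proj.destination)
            n_conn = len(clist)
            if n_conn == 0:
                continue

            wu_comp = project.components[syn.weight_update.component_ref]
            ps_comp = project.components[syn.postsynapse.component_ref]
            wu_props = _sample_binding_properties(
                wu_comp, syn.weight_update.properties, n_conn, master_seed,
                "wu", pi, si)
            if clist.weights is not None:
                target = (clist.recipe.weight_target
                          if clist.recipe is not None
                          and clist.recipe.weight_target else "w")
                wu_props[target] = np.asarray(clist.weights, dtype=np.float64)
            ps_props = _sample_binding_properties(
                ps_comp, syn.postsynapse.properties, n_dst, master_seed,
                "ps", pi, si)
            wu = _Group(f"{label}/weight_update", wu_comp, n_conn, wu_props)
            ps = _Group(f"{label}/postsynapse", ps_comp, n_dst, ps_props)

            src_comp = project.components[
                net.population(proj.source).component_ref]
            dst_comp = project.components[
                net.population(proj.destination).component_ref]
            # spike leg preferred when the source can spike and the
            # weight-update listens for events
            try:
                sp, wrp = _first_compatible(
                    src_comp.send_ports(), wu_comp.receive_ports(), label,
                    ("event",))
                mode = "event"
            except WiringError:
                sp, wrp = _first_compatible(
                    src_comp.send_ports(), wu_comp.receive_ports(), label,
                    ("analog",))
                mode = "analog"
            if mode == "event":
                wsp, prp = _first_compatible(
                    wu_comp.send_ports(), ps_comp.receive_ports(), label,
                    ("impulse", "event"))
            else:
                wsp, prp = _first_compatible(
                    wu_comp.send_ports(), ps_comp.receive_ports(), label,
                    ("analog",))
            psp, nrp = _first_compatible(
                ps_comp.send_ports(), dst_comp.receive_ports(), label,
                ("analog",))

            delay_steps = _quantise_delay(clist.delays(), dt,
                                          event=mode == "event")
            synapses.append(_SynapseRuntime(
                label=label, src_pop=proj.source, dst_pop=proj.destination,
                conn_src=clist.sources(), conn_dst=clist.destinations(),
                delay_steps=delay_steps, wu=wu, ps=ps,
                src_port=sp.name, wu_in_port=wrp.name, wu_out_port=wsp.name,
                ps_in_port=prp.name, ps_out_port=psp.name,
                neuron_in_port=nrp.name, mode=mode))

    gis: list[_GenericInputRuntime] = []
    for gi in net.generic_inputs:
        src_comp = project.components[net.population(gi.source).component_ref]
        sp = src_comp.port(gi.source_port)
        clist = instantiate_connectivity(
            gi.connectivity, sizes[gi.source], sizes[gi.destination],
            seed=derive_seed(master_seed, "gi", gi.source, gi.destination),
            same_population=gi.source == gi.destination)
        mode = "event" if sp.kind == "event" else "analog"
        gis.append(_GenericInputRuntime(
            label=f"input {gi.source}->{gi.destination}",
            src_pop=gi.source, dst_pop=gi.destination,
            src_port=gi.source_port, dst_port=gi.destination_port,
            conn_src=clist.sources(), conn_dst=clist.destinations(),
            delay_steps=_quantise_delay(clist.delays(), dt,
                                        event=mode == "event"),
            mode=mode))

    rt = RuntimeModel(groups, synapses, gis, experiment, dt, n_steps,
                      master_seed)

    for spec in experiment.inputs:
        if isinstance(spec, RegularSpikeInput):
            for t_s in spike_times(spec):
                # a spike nominally at t=0 is delivered on the first step
                step = max(1, int(round(t_s * 1000.0 / dt)))
                rt.spike_schedule.setdefault(step, []).append(spec)
        else:
            rt.analog_inputs.append(spec)
    return rt


# ---------------------------------------------------------------------------
# Stepping
# ---------------------------------------------------------------------------

def _indices_of(indices, n: int) -> np.ndarray:
    if indices is None:
        return np.arange(n)
    return np.asarray(indices, dtype=np.int64)


def run(rt: RuntimeModel) -> LogSet:
    """Run to the experiment duration; returns the collected logs."""
    dt = rt.dt
    logset = LogSet(dt=dt)
    analog_logs: list[tuple[Logger, object, np.ndarray, np.ndarray]] = []
    event_logs: dict[tuple[str, str], list[str]] = {}
    event_buffers: dict[str, tuple[list, list]] = {}

    for logger in rt.experiment.loggers:
        group = rt.populations.get(logger.target)
        if group is None:
            raise SimulationError(
                f"logger {logger.name!r} targets unknown population "
                f"{logger.target!r}")
        logset.loggers[logger.name] = logger
        if logger.kind == "analog":
            idx = _indices_of(logger.indices, group.n)
            buf = np.zeros((rt.n_steps + 1, len(idx)))
            analog_logs.append((logger, group, idx, buf))
        else:
            event_logs.setdefault((logger.target, logger.port),
                                  []).append(logger.name)
            event_buffers[logger.name] = ([], [])

    def record_emissions(pop_name: str, emissions: dict[str, np.ndarray],
                         t_ms: float):
        for port, idx in emissions.items():
            for log_name in event_logs.get((pop_name, port), ()):
                logger = logset.loggers[log_name]
                if logger.indices is not None:
                    keep = np.isin(idx, np.asarray(logger.indices))
                    idx_sel = idx[keep]
                else:
                    idx_sel = idx
                times, inds = event_buffers[log_name]
                times.extend([t_ms / 1000.0] * len(idx_sel))
                inds.extend(int(i) for i in idx_sel)

    # initial sample (t = 0)
    for logger, group, idx, buf in analog_logs:
        buf[0] = group.value_of(logger.port, 0.0)[idx]
    for group in rt.populations.values():
        group.refresh_condition_memory(0.0)
    for syn in rt.synapses:
        syn.wu.refresh_condition_memory(0.0)
        syn.ps.refresh_condition_memory(0.0)

    for k in range(rt.n_steps):
        t_now = k * dt
        t_next = (k + 1) * dt

        # (1) previous-step analog send values per population
        send_env = {name: g.env(t_now) for name, g in rt.populations.items()}

        # (2) propagate through synapses and generic inputs
        new_in: dict[str, dict[str, np.ndarray]] = {
            name: {p: np.zeros(g.n) for p in g.port_in}
            for name, g in rt.populations.items()}
        for syn in rt.synapses:
            if syn.mode == "analog":
                src_vals = rt.populations[syn.src_pop].send_value(
                    syn.src_port, send_env[syn.src_pop])
                wu_in = src_vals[syn.conn_src]
                syn.wu.port_in[syn.wu_in_port] = wu_in
                wu_env = syn.wu.env(t_now)
                wu_out = syn.wu.send_value(syn.wu_out_port, wu_env)
                ps_in = np.zeros(syn.ps.n)
                np.add.at(ps_in, syn.conn_dst, wu_out)
                syn.ps.port_in[syn.ps_in_port] = ps_in
            ps_env = syn.ps.env(t_now)
            ps_out = syn.ps.send_value(syn.ps_out_port, ps_env)
            new_in[syn.dst_pop][syn.neuron_in_port] += ps_out
        for gi in rt.generic_inputs:
            if gi.mode != "analog":
                continue
            src_vals = rt.populations[gi.src_pop].send_value(
                gi.src_port, send_env[gi.src_pop])
            contrib = np.zeros(rt.populations[gi.dst_pop].n)
            np.add.at(contrib, gi.conn_dst, src_vals[gi.conn_src])
            new_in[gi.dst_pop][gi.dst_port] += contrib

        # (3) experiment analog inputs (held value at current time)
        t_s = t_now / 1000.0
        for spec in rt.analog_inputs:
            group = rt.populations[spec.target]
            value = input_value(spec, t_s)
            idx = _indices_of(spec.indices, group.n)
            new_in[spec.target][spec.port][idx] += value

        for name, group in rt.populations.items():
            group.port_in = new_in[name]

        # (4) Euler step everywhere
        for group in rt.populations.values():
            group.euler_step(dt, t_next, k)
        for syn in rt.synapses:
            syn.wu.euler_step(dt, t_next, k)
            syn.ps.euler_step(dt, t_next, k)

        # (5) condition transitions
        for group in rt.populations.values():
            group.fire_conditions(t_next)
        for syn in rt.synapses:
            syn.wu.fire_conditions(t_next)
            syn.ps.fire_conditions(t_next)

        # (6) route condition emissions
        for name, group in rt.populations.items():
            emissions = group.take_emissions()
            record_emissions(name, emissions, t_next)
            _route_population_emissions(rt, name, emissions, k)
        for syn in rt.synapses:
            _route_wu_emissions(rt, syn, syn.wu.take_emissions(), k)
            syn.ps.take_emissions()  # postsynapse→neuron is analog only

        # (7) deliver due events/impulses
        t_deliver = t_next
        for spec in rt.spike_schedule.get(k + 1, ()):
            group = rt.populations[spec.target]
            idx = _indices_of(spec.indices, group.n)
            group.deliver("event", spec.port, idx, None, t_deliver)
        for item in rt.queue.pop(k + 1, ()):
            kind = item[0]
            if kind == "syn_event":
                _, syn, conn_idx = item
                syn.wu.deliver("event", syn.wu_in_port, conn_idx, None,
                               t_deliver)
                _route_wu_emissions(rt, syn, syn.wu.take_emissions(), k)
            elif kind == "pop_event":
                _, pop_name, port, idx = item
                rt.populations[pop_name].deliver("event", port, idx, None,
                                                 t_deliver)
        # cascaded emissions from deliveries
        for name, group in rt.populations.items():
            emissions = group.take_emissions()
            if emissions:
                record_emissions(name, emissions, t_next)
                _route_population_emissions(rt, name, emissions, k)

        # (8) refresh edge memory and log
        for group in rt.populations.values():
            group.refresh_condition_memory(t_next)
        for syn in rt.synapses:
            syn.wu.refresh_condition_memory(t_next)
            syn.ps.refresh_condition_memory(t_next)
        for logger, group, idx, buf in analog_logs:
            buf[k + 1] = group.value_of(logger.port, t_next)[idx]

    times = np.arange(rt.n_steps + 1) * dt / 1000.0
    for logger, group, idx, buf in analog_logs:
        logset.analog[logger.name] = AnalogTrace(times, tuple(int(i)
                                                              for i in idx),
                                                 buf)
    for name, (tlist, ilist) in event_buffers.items():
        logset.events[name] = EventTrace(np.asarray(tlist),
                                         np.asarray(ilist, dtype=np.int64))
    return logset


def _route_population_emissions(rt: RuntimeModel, pop_name: str,
                                emissions: dict[str, np.ndarray], k: int):
    """Queue spikes emitted by a population onto its outgoing connections."""
    for port, fired in emissions.items():
        if len(fired) == 0:
            continue
        for syn in rt.synapses:
            if syn.src_pop != pop_name or syn.mode != "event" \
                    or syn.src_port != port:
                continue
            hit = np.isin(syn.conn_src, fired)
            if not hit.any():
                continue
            conn_idx = np.flatnonzero(hit)
            for d in np.unique(syn.delay_steps[conn_idx]):
                sel = conn_idx[syn.delay_steps[conn_idx] == d]
                rt.queue.setdefault(k + int(d) + 1, []).append(
                    ("syn_event", syn, sel))
        for gi in rt.generic_inputs:
            if gi.src_pop != pop_name or gi.mode != "event" \
                    or gi.src_port != port:
                continue
            hit = np.isin(gi.conn_src, fired)
            if not hit.any():
                continue
            conn_idx = np.flatnonzero(hit)
            for d in np.unique(gi.delay_steps[conn_idx]):
                sel = conn_idx[gi.delay_steps[conn_idx] == d]
                rt.queue.setdefault(k + int(d) + 1, []).append(
                    ("pop_event", gi.dst_pop, gi.dst_port,
                     gi.conn_dst[sel]))


def _route_wu_emissions(rt: RuntimeModel, syn: _SynapseRuntime,
                        emissions: dict[str, np.ndarray], k: int):
    """Weight-update emissions go to the synapse's own postsynapse; the
    connection delay was spent on the spike leg, so transfer is immediate."""
    for port, conn_idx in emissions.items():
        if len(conn_idx) == 0:
            continue
        wu_port = syn.wu.comp.port(port)
        payload = None
        if wu_port is not None and wu_port.kind == "impulse":
            env = syn.wu.env((k + 1) * rt.dt)
            payload = syn.wu.send_value(port, env)[conn_idx]
        syn.ps.deliver(
            "impulse" if payload is not None else "event",
            syn.ps_in_port, syn.conn_dst[conn_idx], payload,
            (k + 1) * rt.dt)


# ---------------------------------------------------------------------------
# External-simulator launch hook
# ---------------------------------------------------------------------------

def run_external_simulator(executable: str, project_dir: str,
                           experiment_name: str,
                           env: dict[str, str] | None = None,
                           timeout: float | None = None):
    """Delegate a run to an external engine via its launch script.

    The contract is minimal: the executable is invoked with the project
    directory and the experiment name as its two arguments, configured
    through environment variables (merged over the current environment).
    The in-process engine (`build_runtime` + `run`) is the reference; this
    hook only hands the same on-disk project to another simulator.
    """
    import subprocess

    merged = dict(os.environ)
    if env:
        merged.update(env)
    return subprocess.run(
        [executable, project_dir, experiment_name],
        env=merged, capture_output=True, text=True, timeout=timeout,
        check=False)


# ---------------------------------------------------------------------------
# Component test bench
# ---------------------------------------------------------------------------

class ComponentBench:
    """Drive a single component in isolation.

    Wraps one instance group with scripted analog drives, event and impulse
    injections, recording every state variable (and requested aliases) at
    each step. Used for closed-form checks of component dynamics.
    """

    def __init__(self, comp: Component, properties: dict[str, float],
                 n: int = 1):
        props = {k: np.full(n, float(v)) for k, v in properties.items()}
        self.group = _Group(comp.name, comp, n, props)
        self.comp = comp
        self.analog_drive: dict[str, object] = {}
        self.impulses: list[tuple[float, str, float, int]] = []
        self.events: list[tuple[float, str, int]] = []

    def set_analog(self, port: str, value):
        """Constant number or callable t_ms -> value."""
        self.analog_drive[port] = value
        return self

    def inject_impulse(self, t_ms: float, port: str, payload: float,
                       index: int = 0):
        self.impulses.append((t_ms, port, payload, index))
        return self

    def inject_event(self, t_ms: float, port: str, index: int = 0):
        self.events.append((t_ms, port, index))
        return self

    def run(self, duration_ms: float, dt: float,
            record: tuple[str, ...] | None = None):
        """Integrate and return {'t': times_ms, name: trace array (steps+1, n)}."""
        g = self.group
        n_steps = int(round(duration_ms / dt))
        names = record if record is not None else g.comp.state_names()
        out = {name: np.zeros((n_steps + 1, g.n)) for name in names}
        times = np.arange(n_steps + 1) * dt

        impulse_steps: dict[int, list] = {}
        for t_ms, port, payload, index in self.impulses:
            impulse_steps.setdefault(int(round(t_ms / dt)), []).append(
                (port, payload, index))
        event_steps: dict[int, list] = {}
        for t_ms, port, index in self.events:
            event_steps.setdefault(int(round(t_ms / dt)), []).append(
                (port, index))

        for name in names:
            out[name][0] = g.value_of(name, 0.0)
        g.refresh_condition_memory(0.0)

        for k in range(n_steps):
            t_now = k * dt
            t_next = (k + 1) * dt
            for port in g.port_in:
                drive = self.analog_drive.get(port, 0.0)
                value = drive(t_now) if callable(drive) else drive
                g.port_in[port] = np.full(g.n, float(value))
            g.euler_step(dt, t_next, k)
            g.fire_conditions(t_next)
            for port, payload, index in impulse_steps.get(k + 1, ()):
                g.deliver("impulse", port, np.array([index]),
                          np.array([float(payload)]), t_next)
            for port, index in event_steps.get(k + 1, ()):
                g.deliver("event", port, np.array([index]), None, t_next)
            g.take_emissions()
            g.refresh_condition_memory(t_next)
            for name in names:
                out[name][k + 1] = g.value_of(name, t_next)
        out["t"] = times
        return out
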