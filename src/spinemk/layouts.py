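"""Procedural 3D layout engine.

Neuron coordinates are generated like frames of an animation: frame p holds
the position of neuron p, frame 0 is the initial state (all layout
variables zero), and a set of equations describes the transition between
adjacent frames, evaluated with the target frame's index ``p`` for
p = 1..n-1. Variables always include x, y and z (micrometres). Reading a
variable inside an equation yields its value from the previous frame unless
it has already been assigned earlier in the current frame's declared
equation order.

``rand()`` draws uniform [0, 1) numbers from a single stream seeded by the
rule (NumPy PCG64, pinned for cross-run determinism). A minimum pairwise
distance can be enforced by rejection: a candidate point closer than the
minimum to any accepted point is re-drawn — re-evaluating the whole
iteration with fresh rand() draws — up to a retry cap.
"""

from __future__ import annotations

import csv
import io
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

import numpy as np

from .expr import parse_expression

__all__ = [
    "LayoutRule",
    "CoordinateSet",
    "PackingError",
    "DeterministicConstraintError",
    "generate_layout",
    "grid_layout",
    "random_box_layout",
    "layout_rule_element",
    "read_layout_rule",
    "coordinates_to_csv",
    "coordinates_from_csv",
]

RETRY_CAP = 10_000  # rejection redraws allowed per point


class PackingError(RuntimeError):
    """min_distance could not be satisfied within the retry cap."""


class DeterministicConstraintError(RuntimeError):
    """A rule without rand() produced a min_distance violation (retrying
    could never help)."""


@dataclass(frozen=True)
class LayoutRule:
    """Per-iteration coordinate-update rule.

    ``variables`` is the ordered declaration list and always contains x, y
    and z; ``equations`` maps (a subset of) those variables to expression
    text over the variables, the iteration index ``p`` and ``rand()``.
    """

    name: str
    equations: tuple[tuple[str, str], ...]
    variables: tuple[str, ...] = ("x", "y", "z")
    seed: int = 0
    min_distance: float = 0.0

    def __post_init__(self):
        for axis in ("x", "y", "z"):
            if axis not in self.variables:
                raise ValueError(f"layout variables must include {axis!r}")
        declared = set(self.variables)
        for var, text in self.equations:
            if var not in declared:
                raise ValueError(f"equation assigns undeclared variable {var!r}")
            expr = parse_expression(text)
            unknown = expr.variables - declared - {"p"}
            if unknown:
                raise ValueError(
                    f"equation for {var!r} references unknown symbol "
                    f"{sorted(unknown)[0]!r}")
        if self.min_distance < 0:
            raise ValueError("min_distance must be >= 0")

    def uses_rand(self) -> bool:
        return any(parse_expression(t).uses_rand for _, t in self.equations)


@dataclass(frozen=True)
class CoordinateSet:
    """(n, 3) array of x, y, z coordinates, index-aligned with neurons."""

    coordinates: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.coordinates, dtype=np.float64)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ValueError("coordinates must have shape (n, 3)")
        arr.setflags(write=False)
        object.__setattr__(self, "coordinates", arr)

    def __len__(self):
        return self.coordinates.shape[0]

    def __eq__(self, other):
        return (isinstance(other, CoordinateSet)
                and np.array_equal(self.coordinates, other.coordinates))

    def as_tuples(self) -> list[tuple[float, float, float]]:
        return [tuple(row) for row in self.coordinates]

    def min_pairwise_distance(self) -> float:
        pts = self.coordinates
        if len(pts) < 2:
            return np.inf
        diff = pts[:, None, :] - pts[None, :, :]
        d = np.sqrt((diff**2).sum(axis=2))
        np.fill_diagonal(d, np.inf)
        return float(d.min())


def generate_layout(rule: LayoutRule, n: int) -> CoordinateSet:
    """Return n frames of the rule's animation: the initial frame plus
    n-1 equation-driven transitions."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rule.seed)
    rand = rng.random
    compiled = [(var, parse_expression(text)) for var, text in rule.equations]
    stochastic = rule.uses_rand()
    d_min = rule.min_distance

    state = {var: 0.0 for var in rule.variables}
    accepted = np.empty((n, 3))
    # frame 0 is the initial state: equations are transitions between
    # adjacent frames, so they run for p = 1..n-1
    accepted[0] = (state["x"], state["y"], state["z"])
    count = 1
    for p in range(1, n):
        attempts = 0
        while True:
            trial = dict(state)
            trial["p"] = float(p)
            assigned: set[str] = set()
            for var, expr in compiled:
                env = {
                    name: (trial[name] if (name in assigned or name == "p")
                           else state.get(name, 0.0))
                    for name in (*rule.variables, "p")
                }
                trial[var] = float(expr(env, rand=rand))
                assigned.add(var)
            point = np.array([trial["x"], trial["y"], trial["z"]])
            if d_min > 0:
                dist = np.sqrt(
                    ((accepted[:count] - point) ** 2).sum(axis=1)
                ).min()
                if dist < d_min:
                    if not stochastic:
                        raise DeterministicConstraintError(
                            f"point {p} violates min_distance {d_min} and the "
                            "rule is deterministic")
                    attempts += 1
                    if attempts >= RETRY_CAP:
                        raise PackingError(
                            f"could not place point {p} within {RETRY_CAP} "
                            f"redraws at min_distance {d_min}")
                    continue
            trial.pop("p")
            state = trial
            accepted[count] = point
            count += 1
            break
    return CoordinateSet(accepted)


def grid_layout(n: int, row_length: int, spacing: float = 1.0,
                name: str = "grid") -> CoordinateSet:
    """Planar grid filled row by row: x = p mod row_length,
    y = floor(p / row_length), z = 0, times the spacing."""
    if row_length < 1:
        raise ValueError("row_length must be >= 1")
    rule = grid_layout_rule(row_length, spacing, name)
    return generate_layout(rule, n)


def grid_layout_rule(row_length: int, spacing: float = 1.0,
                     name: str = "grid") -> LayoutRule:
    r = float(row_length)
    s = float(spacing)
    return LayoutRule(
        name=name,
        equations=(
            ("x", f"mod(p, {r!r}) * {s!r}"),
            ("y", f"floor(p / {r!r}) * {s!r}"),
            ("z", "0"),
        ),
    )


def random_box_layout(n: int, side: float = 300.0, seed: int = 0,
                      min_distance: float = 0.0,
                      name: str = "random_box") -> CoordinateSet:
    """Uniform random points in the cube [0, side)^3 (defaults sized for a
    300 um striatal cube), with optional minimum-distance rejection."""
    return generate_layout(random_box_layout_rule(side, seed, min_distance,
                                                  name), n)


def random_box_layout_rule(side: float = 300.0, seed: int = 0,
                           min_distance: float = 0.0,
                           name: str = "random_box") -> LayoutRule:
    if side <= 0:
        raise ValueError("side must be > 0")
    s = float(side)
    return LayoutRule(
        name=name,
        equations=(
            ("x", f"rand() * {s!r}"),
            ("y", f"rand() * {s!r}"),
            ("z", f"rand() * {s!r}"),
        ),
        seed=seed,
        min_distance=min_distance,
    )


# ---------------------------------------------------------------------------
# Serialisation
# ---------------------------------------------------------------------------

def layout_rule_element(rule: LayoutRule) -> ET.Element:
    el = ET.Element("Layout", {
        "name": rule.name, "seed": str(rule.seed),
        "minimum_distance": repr(rule.min_distance)})
    for var in rule.variables:
        if var not in ("x", "y", "z"):
            ET.SubElement(el, "Variable", {"name": var})
    for var, text in rule.equations:
        eq = ET.SubElement(el, "Equation", {"variable": var})
        eq.text = text
    return el


def read_layout_rule(el: ET.Element) -> LayoutRule:
    if el.tag != "Layout":
        raise ValueError(f"unknown layout tag {el.tag!r}")
    extras = tuple(v.get("name", "") for v in el if v.tag == "Variable")
    equations = tuple(
        (eq.get("variable", ""), (eq.text or "").strip())
        for eq in el if eq.tag == "Equation")
    return LayoutRule(
        name=el.get("name", ""),
        equations=equations,
        variables=("x", "y", "z", *extras),
        seed=int(el.get("seed", "0")),
        min_distance=float(el.get("minimum_distance", "0")),
    )


def coordinates_to_csv(coords: CoordinateSet) -> str:
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(["index", "x", "y", "z"])
    for i, (x, y, z) in enumerate(coords.coordinates):
        writer.writerow([i, repr(float(x)), repr(float(y)), repr(float(z))])
    return buf.getvalue()


def coordinates_from_csv(text: str) -> CoordinateSet:
    reader = csv.reader(io.StringIO(text))
    header = next(reader)
    if [h.strip() for h in header] != ["index", "x", "y", "z"]:
        raise ValueError("expected header index,x,y,z")
    rows = sorted((int(r[0]), float(r[1]), float(r[2]), float(r[3]))
                  for r in reader if r)
    return CoordinateSet(np.array([r[1:] for r in rows], dtype=np.float64)
                         .reshape(len(rows), 3))
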