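"""Pluggable connectivity generation.

A generator is a plain-text Python script whose entry point takes
``srclocs`` and ``dstlocs`` (lists of (x, y, z) tuples) followed by any
number of scalar parameters, and returns a list of connection tuples.
Formatted comment lines at the top describe the parameters for a
configuration UI and declare extra outputs:

    #PARNAME: <label>        one per extra argument, in argument order
    #LOC: <row>,<col>        grid cell for the preceding parameter
    #HASWEIGHT               tuples carry a per-connection weight
    #HASDELAY                tuples carry a per-connection delay (ms)

Returned tuples are ``(src, dst)`` extended by the delay (when #HASDELAY)
and then the weight (when #HASWEIGHT). Scripts run in a restricted
namespace: arithmetic builtins, ``math`` and ``random.Random`` only — no
file or network access.

Generated lists are persisted as fully explicit connection lists so any
reader gets a plain, valid model; the script text, parameter values and
sizes travel alongside inside an Annotations element (the *recipe*) so the
list can be regenerated — and is only regenerated when script text,
parameters or either population size actually change.
"""

from __future__ import annotations

import ast
import hashlib
import math
import random
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass

from .layouts import CoordinateSet
from .network import ANNOTATION_NS, ConnectionList

__all__ = [
    "GeneratorScript",
    "GenerationRecipe",
    "GeneratorMetadataError",
    "GeneratorExecutionError",
    "parse_generator_metadata",
    "run_generator",
    "regenerate",
    "needs_regeneration",
    "recipe_key",
    "persist_with_recipe",
    "load_with_recipe",
    "recipe_annotation",
    "read_recipe_annotation",
    "FIXED_RADIUS_SCRIPT",
    "GAUSSIAN_FIELD_SCRIPT",
    "BUILTIN_SCRIPTS",
]


class GeneratorMetadataError(ValueError):
    pass


class GeneratorExecutionError(RuntimeError):
    def __init__(self, message: str, line: int | None = None):
        super().__init__(message if line is None
                         else f"{message} (script line {line})")
        self.line = line


@dataclass(frozen=True)
class GeneratorScript:
    source_text: str
    entry_name: str
    params: tuple[tuple[str, int, int], ...]  # (label, grid_row, grid_col)
    has_weight: bool = False
    has_delay: bool = False


@dataclass(frozen=True)
class GenerationRecipe:
    """Everything needed to regenerate an identical connection list."""

    source_text: str
    values: tuple[float, ...]
    n_src: int
    n_dst: int
    weight_target: str | None = None  # weight-update property to fill


_PARNAME_RE = re.compile(r"^#\s*PARNAME\s*:\s*(\S.*?)\s*$")
_LOC_RE = re.compile(r"^#\s*LOC\s*:\s*(\d+)\s*,\s*(\d+)\s*$")


def parse_generator_metadata(source_text: str) -> GeneratorScript:
    """Parse the comment metadata and locate the entry point.

    The entry point is the first function whose leading two arguments are
    ``srclocs`` and ``dstlocs``; the number of #PARNAME lines must equal
    its number of extra arguments.
    """
    labels: list[str] = []
    locs: list[tuple[int, int]] = []
    has_weight = False
    has_delay = False
    pending_loc: tuple[int, int] | None = None
    for raw in source_text.splitlines():
        line = raw.strip()
        m = _PARNAME_RE.match(line)
        if m:
            labels.append(m.group(1))
            locs.append((-1, -1))
            continue
        m = _LOC_RE.match(line)
        if m:
            if not labels or locs[-1] != (-1, -1):
                raise GeneratorMetadataError(
                    "#LOC without a preceding #PARNAME")
            locs[-1] = (int(m.group(1)), int(m.group(2)))
            continue
        if line.startswith("#") and line[1:].strip() == "HASWEIGHT":
            has_weight = True
        elif line.startswith("#") and line[1:].strip() == "HASDELAY":
            has_delay = True

    if len(set(labels)) != len(labels):
        raise GeneratorMetadataError("duplicate #PARNAME labels")
    placed = [loc for loc in locs if loc != (-1, -1)]
    if len(set(placed)) != len(placed):
        raise GeneratorMetadataError("duplicate #LOC grid cell")

    try:
        tree = ast.parse(source_text)
    except SyntaxError as exc:
        raise GeneratorMetadataError(f"script does not parse: {exc}") from exc
    entry = None
    for node in tree.body:
        if isinstance(node, ast.FunctionDef):
            args = [a.arg for a in node.args.args]
            if args[:2] == ["srclocs", "dstlocs"]:
                entry = node
                break
    if entry is None:
        raise GeneratorMetadataError(
            "no entry point with leading arguments (srclocs, dstlocs)")
    n_extra = len(entry.args.args) - 2
    if n_extra != len(labels):
        raise GeneratorMetadataError(
            f"{len(labels)} #PARNAME line(s) but entry point "
            f"{entry.name!r} takes {n_extra} extra argument(s)")

    params = tuple(
        (label, *(loc if loc != (-1, -1) else (i, 0)))
        for i, (label, loc) in enumerate(zip(labels, locs)))
    return GeneratorScript(source_text, entry.name, params, has_weight,
                           has_delay)


_SAFE_BUILTINS = {
    "abs": abs, "min": min, "max": max, "len": len, "range": range,
    "enumerate": enumerate, "zip": zip, "float": float, "int": int,
    "sum": sum, "round": round, "sorted": sorted, "list": list,
    "tuple": tuple, "True": True, "False": False,
}


def _exec_namespace() -> dict:
    return {
        "__builtins__": dict(_SAFE_BUILTINS),
        "math": math,
        "Random": random.Random,
    }


def run_generator(
    script: GeneratorScript,
    srclocs: CoordinateSet,
    dstlocs: CoordinateSet,
    values: tuple[float, ...] = (),
    weight_target: str | None = None,
) -> ConnectionList:
    """Execute the script against the coordinate sets and wrap the result
    in a ConnectionList carrying its generation recipe."""
    if len(values) != len(script.params):
        raise ValueError(
            f"expected {len(script.params)} parameter value(s), "
            f"got {len(values)}")
    namespace = _exec_namespace()
    try:
        exec(compile(script.source_text, "<generator>", "exec"), namespace)
        fn = namespace[script.entry_name]
        raw = fn(srclocs.as_tuples(), dstlocs.as_tuples(), *values)
    except Exception as exc:  # wrap with the script line when available
        line = getattr(exc.__traceback__.tb_next, "tb_lineno", None) \
            if exc.__traceback__ is not None else None
        raise GeneratorExecutionError(
            f"generator script failed: {type(exc).__name__}: {exc}",
            line) from exc

    width = 2 + int(script.has_delay) + int(script.has_weight)
    triplets: list[tuple[int, int, float]] = []
    weights: list[float] = []
    n_src, n_dst = len(srclocs), len(dstlocs)
    for row in raw:
        row = tuple(row)
        if len(row) != width:
            raise GeneratorExecutionError(
                f"expected {width}-tuples from the script, got {row!r}")
        s, d = int(row[0]), int(row[1])
        if not (0 <= s < n_src and 0 <= d < n_dst):
            raise GeneratorExecutionError(
                f"connection ({s}, {d}) out of range for sizes "
                f"({n_src}, {n_dst})")
        delay = float(row[2]) if script.has_delay else 0.0
        triplets.append((s, d, delay))
        if script.has_weight:
            weights.append(float(row[2 + int(script.has_delay)]))
    recipe = GenerationRecipe(script.source_text, tuple(float(v) for v in values),
                              n_src, n_dst, weight_target)
    return ConnectionList(tuple(triplets),
                          tuple(weights) if script.has_weight else None,
                          recipe)


def regenerate(recipe: GenerationRecipe, srclocs: CoordinateSet,
               dstlocs: CoordinateSet) -> ConnectionList:
    """Re-run a persisted recipe; bit-identical to the original list for
    identical inputs."""
    script = parse_generator_metadata(recipe.source_text)
    if len(srclocs) != recipe.n_src or len(dstlocs) != recipe.n_dst:
        raise ValueError(
            "coordinate set sizes do not match the recipe "
            f"({len(srclocs)}, {len(dstlocs)}) vs "
            f"({recipe.n_src}, {recipe.n_dst})")
    return run_generator(script, srclocs, dstlocs, recipe.values,
                         recipe.weight_target)


def needs_regeneration(
    recipe: GenerationRecipe,
    current_script_text: str,
    current_values: tuple[float, ...],
    n_src: int,
    n_dst: int,
) -> bool:
    """True iff script text (byte-for-byte), parameter values, or either
    population size changed. A whitespace-only edit counts as a change."""
    return not (
        recipe.source_text == current_script_text
        and tuple(recipe.values) == tuple(float(v) for v in current_values)
        and recipe.n_src == n_src
        and recipe.n_dst == n_dst
    )


def recipe_key(recipe: GenerationRecipe) -> str:
    """SHA-256 cache key over (script text, values, sizes)."""
    h = hashlib.sha256()
    h.update(recipe.source_text.encode())
    h.update(repr(tuple(recipe.values)).encode())
    h.update(f"{recipe.n_src},{recipe.n_dst}".encode())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def _q(tag: str) -> str:
    return f"{{{ANNOTATION_NS}}}{tag}"


def recipe_annotation(recipe: GenerationRecipe) -> ET.Element:
    el = ET.Element(_q("ConnectionRecipe"), {
        "n_src": str(recipe.n_src), "n_dst": str(recipe.n_dst)})
    if recipe.weight_target is not None:
        el.set("weight_target", recipe.weight_target)
    script_el = ET.SubElement(el, _q("Script"))
    script_el.text = recipe.source_text
    for v in recipe.values:
        ET.SubElement(el, _q("ParameterValue"), {"value": repr(float(v))})
    return el


def read_recipe_annotation(annotations: ET.Element) -> GenerationRecipe | None:
    el = annotations.find(_q("ConnectionRecipe"))
    if el is None:
        return None
    script_el = el.find(_q("Script"))
    values = tuple(float(p.get("value", "0"))
                   for p in el.findall(_q("ParameterValue")))
    return GenerationRecipe(
        source_text=script_el.text if script_el is not None else "",
        values=values,
        n_src=int(el.get("n_src", "0")),
        n_dst=int(el.get("n_dst", "0")),
        weight_target=el.get("weight_target"),
    )


def persist_with_recipe(connection_list: ConnectionList,
                        recipe: GenerationRecipe) -> str:
    """Emit a fully explicit ConnectionList fragment plus the recipe inside
    Annotations. Stripping the Annotations leaves a valid plain list."""
    from .network import connectivity_element  # shared element writer
    from dataclasses import replace
    el = connectivity_element(replace(connection_list, recipe=recipe))
    ET.indent(el)
    return ET.tostring(el, encoding="unicode")


def load_with_recipe(text: str) -> ConnectionList:
    """Inverse of persist_with_recipe; restores list and recipe without
    regeneration (the recipe rides on the returned list)."""
    from .network import read_connectivity
    el = ET.fromstring(text)
    scheme = read_connectivity(el)
    if not isinstance(scheme, ConnectionList):
        raise ValueError("fragment is not a ConnectionList")
    return scheme


# ---------------------------------------------------------------------------
# Built-in generator scripts
# ---------------------------------------------------------------------------

FIXED_RADIUS_SCRIPT = '''\
#PARNAME: radius
#LOC: 0,0
#PARNAME: velocity
#LOC: 1,0
#PARNAME: base_delay
#LOC: 2,0
#HASDELAY
def fixed_radius(srclocs, dstlocs, radius, velocity, base_delay):
    """Connect every pair closer than radius (um); delay (ms) is
    distance / velocity (um/ms) + base_delay."""
    conns = []
    for i, (sx, sy, sz) in enumerate(srclocs):
        for j, (dx, dy, dz) in enumerate(dstlocs):
            d = math.sqrt((sx - dx) ** 2 + (sy - dy) ** 2 + (sz - dz) ** 2)
            if d <= radius:
                conns.append((i, j, d / velocity + base_delay))
    return conns
'''

GAUSSIAN_FIELD_SCRIPT = '''\
#PARNAME: sigma
#LOC: 0,0
#PARNAME: amplitude
#LOC: 1,0
#PARNAME: seed
#LOC: 2,0
#HASWEIGHT
def gaussian_field(srclocs, dstlocs, sigma, amplitude, seed):
    """Connect pair (i, j) with probability exp(-d^2 / 2 sigma^2); the
    weight is amplitude times the same Gaussian falloff."""
    rng = Random(int(seed))
    conns = []
    for i, (sx, sy, sz) in enumerate(srclocs):
        for j, (dx, dy, dz) in enumerate(dstlocs):
            d2 = (sx - dx) ** 2 + (sy - dy) ** 2 + (sz - dz) ** 2
            g = math.exp(-d2 / (2.0 * sigma * sigma))
            if rng.random() < g:
                conns.append((i, j, amplitude * g))
    return conns
'''

BUILTIN_SCRIPTS = {
    "fixed_radius": FIXED_RADIUS_SCRIPT,
    "gaussian_field": GAUSSIAN_FIELD_SCRIPT,
}
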