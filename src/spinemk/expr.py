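"""Shared math-expression engine.

Every textual expression in the model stack — alias definitions, time
derivatives, transition triggers and assignments, layout equations — is
parsed by this module into a small AST and compiled once to a Python code
object evaluated against a bindings mapping. Bindings may hold scalars or
NumPy arrays; the generated code uses NumPy ufuncs throughout, so a single
compiled expression evaluates a whole population at once.

Grammar (infix, case-sensitive identifiers):

    ``+ - * /``, ``^`` (power, right-associative), unary minus, parentheses;
    functions ``exp log sin cos sqrt abs floor`` (unary) and
    ``pow min max mod`` (binary); comparisons ``== != < <= > >=``;
    boolean ``&& || !`` (result 0/1).

``rand()`` is a special nullary call: it is only honoured when the caller
supplies a draw function (the layout engine does; component validation
rejects it).
"""

from __future__ import annotations

import re
from functools import lru_cache
from typing import Callable, Mapping

import numpy as np

__all__ = [
    "ExpressionError",
    "ExpressionParseError",
    "ExpressionSymbolError",
    "Expression",
    "parse_expression",
    "evaluate_expression",
]


class ExpressionError(ValueError):
    """Base class for expression failures."""


class ExpressionParseError(ExpressionError):
    """Malformed expression text; carries the character position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class ExpressionSymbolError(ExpressionError):
    """A free identifier could not be resolved."""

    def __init__(self, name: str):
        super().__init__(f"unbound identifier {name!r}")
        self.name = name


_UNARY_FUNCS = {
    "exp": "np.exp",
    "log": "np.log",
    "sin": "np.sin",
    "cos": "np.cos",
    "sqrt": "np.sqrt",
    "abs": "np.abs",
    "floor": "np.floor",
}
_BINARY_FUNCS = {
    "pow": "np.power",
    "min": "np.minimum",
    "max": "np.maximum",
    "mod": "np.mod",
}

_TOKEN_RE = re.compile(
    r"\s*(?:"
    r"(?P<num>(?:\d+\.\d*|\.\d+|\d+)(?:[eE][+-]?\d+)?)"
    r"|(?P<ident>[A-Za-z][A-Za-z0-9_]*)"
    r"|(?P<op>&&|\|\||==|!=|<=|>=|[-+*/^()<>,!])"
    r")"
)


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None or m.end() == pos:
            stripped = text[pos:].lstrip()
            if not stripped:
                break
            raise ExpressionParseError(
                f"unexpected character {stripped[0]!r}", pos
            )
        if m.lastgroup is not None:
            tokens.append((m.lastgroup, m.group(m.lastgroup), m.start(m.lastgroup)))
        pos = m.end()
    tokens.append(("end", "", len(text)))
    return tokens


class _Parser:
    """Recursive-descent parser producing tuple ASTs."""

    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0

    def peek(self):
        return self.tokens[self.i]

    def advance(self):
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def expect_op(self, op: str):
        kind, value, pos = self.peek()
        if kind != "op" or value != op:
            raise ExpressionParseError(f"expected {op!r}", pos)
        self.advance()

    def parse(self):
        node = self.or_expr()
        kind, value, pos = self.peek()
        if kind != "end":
            raise ExpressionParseError(f"unexpected token {value!r}", pos)
        return node

    def or_expr(self):
        node = self.and_expr()
        while self.peek()[:2] == ("op", "||"):
            self.advance()
            node = ("or", node, self.and_expr())
        return node

    def and_expr(self):
        node = self.not_expr()
        while self.peek()[:2] == ("op", "&&"):
            self.advance()
            node = ("and", node, self.not_expr())
        return node

    def not_expr(self):
        if self.peek()[:2] == ("op", "!"):
            self.advance()
            return ("not", self.not_expr())
        return self.comparison()

    def comparison(self):
        node = self.add_expr()
        kind, value, _ = self.peek()
        if kind == "op" and value in ("==", "!=", "<", "<=", ">", ">="):
            self.advance()
            node = ("cmp", value, node, self.add_expr())
        return node

    def add_expr(self):
        node = self.mul_expr()
        while True:
            kind, value, _ = self.peek()
            if kind == "op" and value in "+-":
                self.advance()
                node = ("bin", value, node, self.mul_expr())
            else:
                return node

    def mul_expr(self):
        node = self.unary()
        while True:
            kind, value, _ = self.peek()
            if kind == "op" and value in "*/":
                self.advance()
                node = ("bin", value, node, self.unary())
            else:
                return node

    def unary(self):
        if self.peek()[:2] == ("op", "-"):
            self.advance()
            return ("neg", self.unary())
        if self.peek()[:2] == ("op", "+"):
            self.advance()
            return self.unary()
        return self.power()

    def power(self):
        base = self.atom()
        if self.peek()[:2] == ("op", "^"):
            self.advance()
            return ("bin", "^", base, self.unary())  # right-associative
        return base

    def atom(self):
        kind, value, pos = self.advance()
        if kind == "num":
            return ("num", float(value))
        if kind == "ident":
            if self.peek()[:2] == ("op", "("):
                self.advance()
                args = []
                if self.peek()[:2] != ("op", ")"):
                    args.append(self.or_expr())
                    while self.peek()[:2] == ("op", ","):
                        self.advance()
                        args.append(self.or_expr())
                self.expect_op(")")
                return self._call(value, args, pos)
            return ("var", value)
        if kind == "op" and value == "(":
            node = self.or_expr()
            self.expect_op(")")
            return node
        raise ExpressionParseError(f"unexpected token {value!r}", pos)

    @staticmethod
    def _call(name: str, args: list, pos: int):
        if name == "rand":
            if args:
                raise ExpressionParseError("rand() takes no arguments", pos)
            return ("rand",)
        if name in _UNARY_FUNCS:
            if len(args) != 1:
                raise ExpressionParseError(f"{name}() takes 1 argument", pos)
            return ("call", name, tuple(args))
        if name in _BINARY_FUNCS:
            if len(args) != 2:
                raise ExpressionParseError(f"{name}() takes 2 arguments", pos)
            return ("call", name, tuple(args))
        raise ExpressionParseError(f"unknown function {name!r}", pos)


def _free_vars(node, out: set, rand_flag: list):
    tag = node[0]
    if tag == "var":
        out.add(node[1])
    elif tag == "rand":
        rand_flag.append(True)
    elif tag == "call":
        for a in node[2]:
            _free_vars(a, out, rand_flag)
    elif tag in ("bin", "cmp"):
        _free_vars(node[2], out, rand_flag)
        _free_vars(node[3], out, rand_flag)
    elif tag in ("and", "or"):
        _free_vars(node[1], out, rand_flag)
        _free_vars(node[2], out, rand_flag)
    elif tag in ("neg", "not"):
        _free_vars(node[1], out, rand_flag)


def _codegen(node) -> str:
    tag = node[0]
    if tag == "num":
        return repr(node[1])
    if tag == "var":
        return f"_b[{node[1]!r}]"
    if tag == "rand":
        return "_rand()"
    if tag == "call":
        fn = _UNARY_FUNCS.get(node[1]) or _BINARY_FUNCS[node[1]]
        return f"{fn}({', '.join(_codegen(a) for a in node[2])})"
    if tag == "bin":
        op = node[1]
        left, right = _codegen(node[2]), _codegen(node[3])
        if op == "^":
            return f"np.power({left}, {right})"
        return f"({left} {op} {right})"
    if tag == "neg":
        return f"(-{_codegen(node[1])})"
    if tag == "cmp":
        return f"({_codegen(node[2])} {node[1]} {_codegen(node[3])})"
    if tag == "and":
        return f"np.logical_and({_codegen(node[1])}, {_codegen(node[2])})"
    if tag == "or":
        return f"np.logical_or({_codegen(node[1])}, {_codegen(node[2])})"
    if tag == "not":
        return f"np.logical_not({_codegen(node[1])})"
    raise AssertionError(node)


class Expression:
    """A parsed, compiled expression.

    Attributes
    ----------
    text : str
        Original source text.
    variables : frozenset[str]
        Free identifiers (``rand`` excluded).
    uses_rand : bool
        Whether the expression calls ``rand()``.
    """

    __slots__ = ("text", "variables", "uses_rand", "_code")

    def __init__(self, text: str):
        ast = _Parser(text).parse()
        free: set = set()
        rand_flag: list = []
        _free_vars(ast, free, rand_flag)
        self.text = text
        self.variables = frozenset(free)
        self.uses_rand = bool(rand_flag)
        self._code = compile(_codegen(ast), "<expression>", "eval")

    def __call__(
        self,
        bindings: Mapping[str, object],
        rand: Callable[[], float] | None = None,
    ):
        missing = self.variables.difference(bindings)
        if missing:
            raise ExpressionSymbolError(sorted(missing)[0])
        if self.uses_rand and rand is None:
            raise ExpressionSymbolError("rand")
        with np.errstate(all="ignore"):
            value = eval(  # noqa: S307 - code generated by this module only
                self._code, {"np": np, "_b": bindings, "_rand": rand}, {}
            )
        if isinstance(value, np.ndarray):
            if value.dtype == bool:
                return value.astype(np.float64)
            return value
        if isinstance(value, (bool, np.bool_)):
            return float(value)
        return float(value)

    def __repr__(self):
        return f"Expression({self.text!r})"

    def __eq__(self, other):
        return isinstance(other, Expression) and self.text == other.text

    def __hash__(self):
        return hash(self.text)


@lru_cache(maxsize=4096)
def parse_expression(text: str) -> Expression:
    """Parse (with caching) expression source into a compiled Expression."""
    return Expression(text)


@lru_cache(maxsize=1024)
def additive_increment(text: str, var: str) -> Expression | None:
    """If ``text`` has the form ``var + f`` or ``f + var`` with ``f`` not
    referencing ``var``, return ``f`` compiled; else None.

    Lets the simulator apply simultaneous increments (several impulses
    hitting one target in a step) with an unordered scatter-add instead of
    a serial loop.
    """
    ast = _Parser(text).parse()
    if ast[0] != "bin" or ast[1] != "+":
        return None
    for var_side, f_side in ((ast[2], ast[3]), (ast[3], ast[2])):
        if var_side == ("var", var):
            free: set = set()
            _free_vars(f_side, free, [])
            if var not in free:
                return parse_expression(_codegen_to_text(f_side))
    return None


def _codegen_to_text(node) -> str:
    """Render an AST back to grammar text (used only for sub-expressions)."""
    tag = node[0]
    if tag == "num":
        return repr(node[1])
    if tag == "var":
        return node[1]
    if tag == "rand":
        return "rand()"
    if tag == "call":
        return f"{node[1]}({', '.join(_codegen_to_text(a) for a in node[2])})"
    if tag == "bin":
        return f"({_codegen_to_text(node[2])} {node[1]} {_codegen_to_text(node[3])})"
    if tag == "cmp":
        return f"({_codegen_to_text(node[2])} {node[1]} {_codegen_to_text(node[3])})"
    if tag == "and":
        return f"({_codegen_to_text(node[1])} && {_codegen_to_text(node[2])})"
    if tag == "or":
        return f"({_codegen_to_text(node[1])} || {_codegen_to_text(node[2])})"
    if tag == "not":
        return f"(!{_codegen_to_text(node[1])})"
    raise AssertionError(node)


def evaluate_expression(
    text: str,
    bindings: Mapping[str, object] | None = None,
    rand: Callable[[], float] | None = None,
):
    """One-shot parse and evaluate; booleans come back as 0/1 floats."""
    return parse_expression(text)(bindings or {}, rand=rand)
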