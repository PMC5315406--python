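"""Arithmetic expression trees for kinetic laws.

A deliberately small language: numbers, symbols, ``+ - * /`` and ``**``.
This covers mass-action and Hill/Michaelis-style rate laws. Trees can be
read from and written to the content-MathML subset used by SBML kinetic
laws, or parsed from plain infix text. Anything outside the subset
(piecewise, csymbol, function application, ...) is rejected loudly.
"""

from __future__ import annotations

import ast
import math
from dataclasses import dataclass
from typing import Iterator, Mapping
from xml.etree import ElementTree as ET

MATHML_NS = "http://www.w3.org/1998/Math/MathML"


class ExprError(ValueError):
    """Raised for unsupported or malformed expression content."""


@dataclass(frozen=True)
class Expr:
    """Base class for expression nodes."""

    def evaluate(self, env: Mapping[str, float]) -> float:
        raise NotImplementedError

    def symbols(self) -> set[str]:
        return set(s for s in self._iter_symbols())

    def _iter_symbols(self) -> Iterator[str]:
        return iter(())

    def to_infix(self) -> str:
        raise NotImplementedError

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_infix()


@dataclass(frozen=True)
class Num(Expr):
    value: float

    def evaluate(self, env: Mapping[str, float]) -> float:
        return self.value

    def to_infix(self) -> str:
        return repr(self.value)


@dataclass(frozen=True)
class Sym(Expr):
    name: str

    def evaluate(self, env: Mapping[str, float]) -> float:
        try:
            return env[self.name]
        except KeyError:
            raise ExprError(f"unbound symbol {self.name!r}") from None

    def _iter_symbols(self) -> Iterator[str]:
        yield self.name

    def to_infix(self) -> str:
        return self.name


@dataclass(frozen=True)
class Neg(Expr):
    operand: Expr

    def evaluate(self, env: Mapping[str, float]) -> float:
        return -self.operand.evaluate(env)

    def _iter_symbols(self) -> Iterator[str]:
        yield from self.operand._iter_symbols()

    def to_infix(self) -> str:
        return f"(-{self.operand.to_infix()})"


@dataclass(frozen=True)
class BinOp(Expr):
    op: str  # one of + - * / **
    left: Expr
    right: Expr

    _FUNCS = {
        "+": lambda a, b: a + b,
        "-": lambda a, b: a - b,
        "*": lambda a, b: a * b,
        "/": lambda a, b: a / b,
        "**": lambda a, b: math.pow(a, b) if not (a < 0 and b != int(b)) else float("nan"),
    }

    def evaluate(self, env: Mapping[str, float]) -> float:
        return self._FUNCS[self.op](self.left.evaluate(env), self.right.evaluate(env))

    def _iter_symbols(self) -> Iterator[str]:
        yield from self.left._iter_symbols()
        yield from self.right._iter_symbols()

    def to_infix(self) -> str:
        return f"({self.left.to_infix()} {self.op} {self.right.to_infix()})"


def add(*args: Expr) -> Expr:
    out = args[0]
    for a in args[1:]:
        out = BinOp("+", out, a)
    return out


def mul(*args: Expr) -> Expr:
    out = args[0]
    for a in args[1:]:
        out = BinOp("*", out, a)
    return out


# ---------------------------------------------------------------------------
# infix text <-> tree (via the Python ast module, arithmetic nodes only)

_AST_BINOPS = {ast.Add: "+", ast.Sub: "-", ast.Mult: "*", ast.Div: "/", ast.Pow: "**"}


def parse_infix(text: str) -> Expr:
    """Parse infix arithmetic like ``a5 * R / (k9 + R)`` into a tree."""
    try:
        node = ast.parse(text, mode="eval").body
    except SyntaxError as exc:
        raise ExprError(f"cannot parse expression {text!r}: {exc}") from None
    return _from_ast(node)


def _from_ast(node: ast.AST) -> Expr:
    if isinstance(node, ast.Constant):
        if not isinstance(node.value, (int, float)):
            raise ExprError(f"unsupported constant {node.value!r}")
        return Num(float(node.value))
    if isinstance(node, ast.Name):
        return Sym(node.id)
    if isinstance(node, ast.UnaryOp) and isinstance(node.op, ast.USub):
        return Neg(_from_ast(node.operand))
    if isinstance(node, ast.UnaryOp) and isinstance(node.op, ast.UAdd):
        return _from_ast(node.operand)
    if isinstance(node, ast.BinOp):
        op = _AST_BINOPS.get(type(node.op))
        if op is None:
            raise ExprError(f"unsupported operator {type(node.op).__name__}")
        return BinOp(op, _from_ast(node.left), _from_ast(node.right))
    raise ExprError(f"unsupported syntax {type(node).__name__}")


# ---------------------------------------------------------------------------
# MathML subset <-> tree

_MATHML_OPS = {"plus": "+", "minus": "-", "times": "*", "divide": "/", "power": "**"}


def _strip_ns(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def from_mathml(elem: ET.Element) -> Expr:
    """Convert a content-MathML element (``<math>`` or its child) to a tree."""
    tag = _strip_ns(elem.tag)
    if tag == "math":
        children = list(elem)
        if len(children) != 1:
            raise ExprError("<math> must contain exactly one expression")
        return from_mathml(children[0])
    if tag == "ci":
        return Sym((elem.text or "").strip())
    if tag == "cn":
        return Num(_parse_cn(elem))
    if tag == "apply":
        children = list(elem)
        if not children:
            raise ExprError("empty <apply>")
        op_tag = _strip_ns(children[0].tag)
        args = [from_mathml(c) for c in children[1:]]
        if op_tag not in _MATHML_OPS:
            raise ExprError(f"unsupported MathML operator <{op_tag}>")
        op = _MATHML_OPS[op_tag]
        if op == "-" and len(args) == 1:
            return Neg(args[0])
        if not args:
            raise ExprError(f"<apply><{op_tag}/> with no operands")
        if op in ("+", "*"):
            out = args[0]
            for a in args[1:]:
                out = BinOp(op, out, a)
            return out
        if len(args) != 2:
            raise ExprError(f"<{op_tag}> expects 2 operands, got {len(args)}")
        return BinOp(op, args[0], args[1])
    raise ExprError(f"unsupported MathML construct <{tag}>")


def _parse_cn(elem: ET.Element) -> float:
    cn_type = elem.get("type", "real")
    if cn_type == "e-notation":
        mantissa = (elem.text or "").strip()
        sep = elem.find(f"{{{MATHML_NS}}}sep")
        if sep is None or sep.tail is None:
            raise ExprError("e-notation <cn> missing <sep/> exponent")
        return float(f"{mantissa}e{sep.tail.strip()}")
    if cn_type in ("real", "integer", "double"):
        return float((elem.text or "").strip())
    raise ExprError(f"unsupported <cn type={cn_type!r}>")


def to_mathml(expr: Expr) -> ET.Element:
    """Render a tree as a ``<math>`` element in the MathML namespace."""
    math_el = ET.Element(f"{{{MATHML_NS}}}math")
    math_el.append(_to_mathml_node(expr))
    return math_el


_OP_TAGS = {v: k for k, v in _MATHML_OPS.items()}


def _to_mathml_node(expr: Expr) -> ET.Element:
    ns = f"{{{MATHML_NS}}}"
    if isinstance(expr, Num):
        el = ET.Element(ns + "cn")
        v = expr.value
        if v == int(v) and abs(v) < 1e15:
            el.set("type", "integer")
            el.text = str(int(v))
        else:
            el.text = repr(v)
        return el
    if isinstance(expr, Sym):
        el = ET.Element(ns + "ci")
        el.text = f" {expr.name} "
        return el
    if isinstance(expr, Neg):
        el = ET.Element(ns + "apply")
        el.append(ET.Element(ns + "minus"))
        el.append(_to_mathml_node(expr.operand))
        return el
    if isinstance(expr, BinOp):
        el = ET.Element(ns + "apply")
        el.append(ET.Element(ns + _OP_TAGS[expr.op]))
        el.append(_to_mathml_node(expr.left))
        el.append(_to_mathml_node(expr.right))
        return el
    raise ExprError(f"cannot serialise {type(expr).__name__}")


def compile_expr(expr: Expr, arg_names: list[str]) -> "callable":
    """Compile a tree to a fast positional-argument Python function."""
    src = f"lambda {', '.join(arg_names)}: {expr.to_infix()}"
    return eval(src, {"__builtins__": {}})  # noqa: S307 - source is generated
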