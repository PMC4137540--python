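"""Safe arithmetic expression grammar for reaction rate laws.

Rate expressions are plain strings over species, parameter and input names,
combined with ``+ - * / **``, numeric literals, parentheses, and a single
domain function ``hill(x, K, n) = x**n / (K**n + x**n)``.  Expressions are
parsed with :mod:`ast` and validated against a whitelist of node types, so a
model file can never execute arbitrary code.
"""

from __future__ import annotations

import ast
import math
from typing import Callable, Iterable, Mapping

__all__ = ["hill", "compile_expression", "expression_symbols", "ExpressionError"]


def hill(x: float, K: float, n: float) -> float:
    """Activating Hill function ``x**n / (K**n + x**n)``, 0 at x=0, →1 as x→∞."""
    if x <= 0.0:
        return 0.0
    xn = x ** n
    return xn / (K ** n + xn)


_FUNCTIONS: dict[str, Callable] = {
    "hill": hill,
    "exp": math.exp,
    "log": math.log,
    "sqrt": math.sqrt,
    "min": min,
    "max": max,
    "abs": abs,
}

_ALLOWED_NODES = (
    ast.Expression,
    ast.BinOp,
    ast.UnaryOp,
    ast.Add,
    ast.Sub,
    ast.Mult,
    ast.Div,
    ast.Pow,
    ast.USub,
    ast.UAdd,
    ast.Num,
    ast.Constant,
    ast.Name,
    ast.Load,
    ast.Call,
)


class ExpressionError(ValueError):
    """Raised for a malformed or unsafe rate expression."""


def _validate(tree: ast.Expression, source: str) -> None:
    for node in ast.walk(tree):
        if not isinstance(node, _ALLOWED_NODES):
            raise ExpressionError(
                f"disallowed syntax {type(node).__name__!r} in rate expression {source!r}"
            )
        if isinstance(node, ast.Call):
            if not isinstance(node.func, ast.Name) or node.func.id not in _FUNCTIONS:
                raise ExpressionError(f"unknown function call in {source!r}")
            if node.keywords:
                raise ExpressionError(f"keyword arguments not supported in {source!r}")
        if isinstance(node, ast.Constant) and not isinstance(node.value, (int, float)):
            raise ExpressionError(f"non-numeric literal in {source!r}")


def expression_symbols(source: str) -> set[str]:
    """Names referenced by the expression, excluding built-in functions."""
    try:
        tree = ast.parse(source, mode="eval")
    except SyntaxError as exc:
        raise ExpressionError(f"cannot parse rate expression {source!r}: {exc}") from exc
    _validate(tree, source)
    return {
        node.id
        for node in ast.walk(tree)
        if isinstance(node, ast.Name) and node.id not in _FUNCTIONS
    }


def compile_expression(source: str, allowed_symbols: Iterable[str]) -> Callable[[Mapping[str, float]], float]:
    """Compile an expression string into ``f(namespace) -> float``.

    Every free symbol must appear in *allowed_symbols*; the returned callable
    evaluates the expression against a name → value mapping.
    """
    symbols = expression_symbols(source)
    unknown = symbols - set(allowed_symbols)
    if unknown:
        raise ExpressionError(
            f"unknown symbol(s) {sorted(unknown)} in rate expression {source!r}"
        )
    code = compile(ast.parse(source, mode="eval"), f"<rate:{source}>", "eval")
    env = {"__builtins__": {}, **_FUNCTIONS}

    def evaluate(namespace: Mapping[str, float]) -> float:
        # locals may be any mapping; avoid copying on the ODE hot path
        return eval(code, env, namespace)

    evaluate.source = source  # type: ignore[attr-defined]
    evaluate.symbols = symbols  # type: ignore[attr-defined]
    return evaluate
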