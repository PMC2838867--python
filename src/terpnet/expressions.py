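"""Restricted arithmetic/boolean expression grammar for HFPNe speeds and thresholds.

Speed formulae, arc thresholds, and generic update rules are stored as strings
in a small expression language: numeric and boolean literals, named parameters,
place references, ``+ - * /``, unary minus, ``min``/``max``/``abs``, comparisons,
``and``/``or``/``not`` and ``x if cond else y``. The special names ``time`` and
``dt`` refer to the current simulation time and integration step.

Expressions are parsed with :mod:`ast`, validated against a node whitelist, and
compiled once; evaluation is a pure function of the provided namespace, so two
evaluations with identical inputs return identical results. Python booleans
coerce to 0/1 in arithmetic, which is how on/off switches gate reaction speeds
multiplicatively.
"""

from __future__ import annotations

import ast
from dataclasses import dataclass, field


class ExpressionError(ValueError):
    """Raised for grammar violations, unknown identifiers, or evaluation faults."""


_ALLOWED_NODES = (
    ast.Expression,
    ast.Constant,
    ast.Name,
    ast.Load,
    ast.BinOp,
    ast.Add,
    ast.Sub,
    ast.Mult,
    ast.Div,
    ast.UnaryOp,
    ast.USub,
    ast.UAdd,
    ast.Not,
    ast.BoolOp,
    ast.And,
    ast.Or,
    ast.Compare,
    ast.Lt,
    ast.LtE,
    ast.Gt,
    ast.GtE,
    ast.Eq,
    ast.NotEq,
    ast.IfExp,
    ast.Call,
)

_ALLOWED_CALLS = {"min": min, "max": max, "abs": abs}

#: Names always available during evaluation (besides places and parameters).
RESERVED_NAMES = frozenset({"time", "dt", "True", "False"}) | frozenset(_ALLOWED_CALLS)


@dataclass(frozen=True)
class CompiledExpression:
    """A validated, compiled expression ready for repeated evaluation."""

    source: str
    names: frozenset[str]
    _code: object = field(repr=False, compare=False)

    def evaluate(self, namespace: dict):
        """Evaluate against ``namespace`` (place markings, parameters, time, dt)."""
        try:
            return eval(self._code, _EVAL_GLOBALS, namespace)  # noqa: S307 - whitelisted AST
        except NameError as exc:
            raise ExpressionError(
                f"unknown identifier {exc.name!r} in expression {self.source!r}"
            ) from exc
        except ZeroDivisionError as exc:
            raise ExpressionError(f"division by zero in expression {self.source!r}") from exc


_EVAL_GLOBALS = {"__builtins__": {}, **_ALLOWED_CALLS}


def compile_expression(source) -> CompiledExpression:
    """Parse, validate and compile an expression string (numbers pass through).

    Raises :class:`ExpressionError` if the source uses any construct outside
    the restricted grammar (attribute access, subscripts, power, imports, ...).
    """
    if isinstance(source, CompiledExpression):
        return source
    if isinstance(source, bool) or not isinstance(source, str):
        source = repr(source)
    try:
        tree = ast.parse(source, mode="eval")
    except SyntaxError as exc:
        raise ExpressionError(f"cannot parse expression {source!r}: {exc.msg}") from exc

    names: set[str] = set()
    for node in ast.walk(tree):
        if not isinstance(node, _ALLOWED_NODES):
            raise ExpressionError(
                f"disallowed construct {type(node).__name__!r} in expression {source!r}"
            )
        if isinstance(node, ast.Call):
            if not isinstance(node.func, ast.Name) or node.func.id not in _ALLOWED_CALLS:
                raise ExpressionError(f"only min/max/abs calls allowed, in {source!r}")
            if node.keywords:
                raise ExpressionError(f"keyword arguments not allowed, in {source!r}")
        if isinstance(node, ast.Constant) and not isinstance(node.value, (int, float, bool)):
            raise ExpressionError(f"non-numeric literal {node.value!r} in {source!r}")
        if isinstance(node, ast.Name):
            names.add(node.id)

    code = compile(tree, "<terpnet-expression>", "eval")
    return CompiledExpression(source=source, names=frozenset(names - set(_ALLOWED_CALLS)), _code=code)


def evaluate_expression(expr, state, parameters: dict | None = None, dt: float = 0.0):
    """Evaluate ``expr`` for a simulation state.

    ``state`` may be a :class:`terpnet.engine.SimState` or a plain mapping of
    names to values. Parameters are overridden by place markings on name
    collision (networks are validated to avoid collisions).
    """
    namespace = dict(parameters or {})
    marking = getattr(state, "marking", state)
    namespace.update(marking)
    namespace["time"] = getattr(state, "time", namespace.get("time", 0.0))
    namespace["dt"] = dt
    return compile_expression(expr).evaluate(namespace)
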