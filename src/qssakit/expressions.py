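"""Whitelisted arithmetic expression grammar for rate laws.

Closed-form (non-elementary) rate laws -- Hill functions, Michaelis-Menten
terms, the total-QSS quadratic root -- are declared as strings over a small
grammar: ``+ - * / ** sqrt``, numbers, and named species/parameters.  The
same parsed expression drives three consumers:

* a plain Python callable over a state vector (deterministic derivatives),
* a stack bytecode program executed inside the numba SSA kernel,
* symbolic substitution (conservation-law elimination, parameter binding).

Arbitrary Python is rejected at parse time; only the node types below are
admitted, so expressions loaded from user configuration files are safe to
evaluate.
"""

from __future__ import annotations

import ast
from dataclasses import dataclass

import numpy as np

__all__ = ["Expr", "ExpressionError", "parse_expression"]

# bytecode opcodes shared with the numba kernel (see _ssa_kernel)
OP_CONST = 0
OP_SPECIES = 1
OP_ADD = 2
OP_SUB = 3
OP_MUL = 4
OP_DIV = 5
OP_POW = 6
OP_SQRT = 7
OP_NEG = 8

_ALLOWED_BINOPS = {
    ast.Add: OP_ADD,
    ast.Sub: OP_SUB,
    ast.Mult: OP_MUL,
    ast.Div: OP_DIV,
    ast.Pow: OP_POW,
}

_ALLOWED_CALLS = {"sqrt"}


class ExpressionError(ValueError):
    """Raised for expressions outside the whitelisted grammar."""


def _validate(node: ast.AST) -> None:
    if isinstance(node, ast.Expression):
        _validate(node.body)
    elif isinstance(node, ast.BinOp):
        if type(node.op) not in _ALLOWED_BINOPS:
            raise ExpressionError(f"operator {type(node.op).__name__} not allowed")
        _validate(node.left)
        _validate(node.right)
    elif isinstance(node, ast.UnaryOp):
        if not isinstance(node.op, (ast.USub, ast.UAdd)):
            raise ExpressionError("only unary +/- allowed")
        _validate(node.operand)
    elif isinstance(node, ast.Call):
        if not (isinstance(node.func, ast.Name) and node.func.id in _ALLOWED_CALLS):
            raise ExpressionError("only sqrt() calls are allowed")
        if len(node.args) != 1 or node.keywords:
            raise ExpressionError("sqrt takes exactly one positional argument")
        _validate(node.args[0])
    elif isinstance(node, ast.Name):
        pass
    elif isinstance(node, ast.Constant):
        if not isinstance(node.value, (int, float)):
            raise ExpressionError(f"constant {node.value!r} is not numeric")
    else:
        raise ExpressionError(f"node {type(node).__name__} not allowed")


class _Substituter(ast.NodeTransformer):
    def __init__(self, mapping: dict[str, ast.expr]):
        self.mapping = mapping

    def visit_Name(self, node: ast.Name):  # noqa: N802
        repl = self.mapping.get(node.id)
        if repl is None:
            return node
        return ast.copy_location(repl, node)


@dataclass(frozen=True)
class Expr:
    """A validated arithmetic expression over named quantities."""

    tree: ast.Expression
    text: str

    @property
    def names(self) -> frozenset[str]:
        return frozenset(
            n.id for n in ast.walk(self.tree) if isinstance(n, ast.Name) and n.id != "sqrt"
        )

    def substitute(self, mapping: dict[str, "Expr | float | int"]) -> "Expr":
        """Replace names by sub-expressions or numeric constants."""
        repl: dict[str, ast.expr] = {}
        for name, value in mapping.items():
            if isinstance(value, Expr):
                repl[name] = value.tree.body
            else:
                repl[name] = ast.Constant(float(value))
        new = _Substituter(repl).visit(ast.parse(ast.unparse(self.tree), mode="eval"))
        ast.fix_missing_locations(new)
        return Expr(new, ast.unparse(new))

    def compile(self, order: list[str]):
        """Return ``f(state_vector) -> float`` with names mapped to indices.

        Every free name must appear in ``order``; bind parameters to numeric
        values with :meth:`substitute` first.
        """
        idx = {name: i for i, name in enumerate(order)}
        missing = self.names - set(idx)
        if missing:
            raise ExpressionError(f"unbound names in expression: {sorted(missing)}")

        class _Indexer(ast.NodeTransformer):
            def visit_Name(self, node: ast.Name):  # noqa: N802
                if node.id == "sqrt":
                    return node
                return ast.copy_location(
                    ast.Subscript(
                        value=ast.Name(id="_x", ctx=ast.Load()),
                        slice=ast.Constant(idx[node.id]),
                        ctx=ast.Load(),
                    ),
                    node,
                )

        body = _Indexer().visit(ast.parse(ast.unparse(self.tree), mode="eval"))
        fn = ast.Expression(
            body=ast.Lambda(
                args=ast.arguments(
                    posonlyargs=[],
                    args=[ast.arg(arg="_x")],
                    kwonlyargs=[],
                    kw_defaults=[],
                    defaults=[],
                ),
                body=body.body,
            )
        )
        ast.fix_missing_locations(fn)
        code = compile(fn, "<rate-law>", "eval")
        return eval(code, {"sqrt": np.sqrt, "__builtins__": {}})  # noqa: S307

    def bytecode(self, order: list[str]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Postorder stack program: (opcodes, int args, float consts)."""
        idx = {name: i for i, name in enumerate(order)}
        missing = self.names - set(idx)
        if missing:
            raise ExpressionError(f"unbound names in expression: {sorted(missing)}")
        ops: list[int] = []
        args: list[int] = []
        consts: list[float] = []

        def emit(node: ast.AST) -> None:
            if isinstance(node, ast.BinOp):
                emit(node.left)
                emit(node.right)
                ops.append(_ALLOWED_BINOPS[type(node.op)])
                args.append(0)
            elif isinstance(node, ast.UnaryOp):
                emit(node.operand)
                if isinstance(node.op, ast.USub):
                    ops.append(OP_NEG)
                    args.append(0)
            elif isinstance(node, ast.Call):
                emit(node.args[0])
                ops.append(OP_SQRT)
                args.append(0)
            elif isinstance(node, ast.Name):
                ops.append(OP_SPECIES)
                args.append(idx[node.id])
            elif isinstance(node, ast.Constant):
                ops.append(OP_CONST)
                args.append(len(consts))
                consts.append(float(node.value))
            else:  # pragma: no cover - guarded by _validate
                raise ExpressionError(type(node).__name__)

        emit(self.tree.body)
        return (
            np.asarray(ops, dtype=np.int32),
            np.asarray(args, dtype=np.int32),
            np.asarray(consts, dtype=np.float64),
        )

    def __str__(self) -> str:
        return self.text


def parse_expression(text: "str | float | int | Expr") -> Expr:
    """Parse and validate an expression in the whitelisted grammar."""
    if isinstance(text, Expr):
        return text
    if isinstance(text, (int, float)):
        text = repr(float(text))
    try:
        tree = ast.parse(text, mode="eval")
    except SyntaxError as exc:
        raise ExpressionError(f"cannot parse {text!r}: {exc}") from exc
    _validate(tree)
    return Expr(tree, ast.unparse(tree))
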