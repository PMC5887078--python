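"""A small, safe expression language over named per-taxon/per-record variables.

This is the analog of referring to data fields as bare variables in a verb
call: an expression such as ``taxon_names == 'Fungi'`` or ``n_subtaxa > 10``
is parsed with the Python grammar but evaluated against a restricted node
whitelist, so no attribute access, subscripting, imports or arbitrary calls
are possible.  Names resolve through a caller-supplied function, which is
how call-time re-resolution works: every evaluation sees the current state
of the object, never a cached value.

Grammar (Python syntax, vectorised over numpy arrays):
  comparisons   ==  !=  <  <=  >  >=  in  not in
  boolean ops   and  or  not       (element-wise)
  arithmetic    +  -  *  /  %      and unary -
  literals      numbers, strings, True/False/None, lists/tuples of literals
  calls         isna(x), notna(x) only
"""

from __future__ import annotations

import ast
from typing import Callable

import numpy as np
import pandas as pd

__all__ = ["evaluate", "ExpressionError"]


class ExpressionError(ValueError):
    pass


_ALLOWED_FUNCS = {
    "isna": lambda x: pd.isna(np.asarray(x, dtype=object)),
    "notna": lambda x: ~pd.isna(np.asarray(x, dtype=object)),
}

_CMP = {
    ast.Eq: lambda a, b: a == b,
    ast.NotEq: lambda a, b: a != b,
    ast.Lt: lambda a, b: a < b,
    ast.LtE: lambda a, b: a <= b,
    ast.Gt: lambda a, b: a > b,
    ast.GtE: lambda a, b: a >= b,
}

_BINOP = {
    ast.Add: lambda a, b: a + b,
    ast.Sub: lambda a, b: a - b,
    ast.Mult: lambda a, b: a * b,
    ast.Div: lambda a, b: a / b,
    ast.Mod: lambda a, b: a % b,
}


def _as_array(x):
    if isinstance(x, pd.Series):
        return x.to_numpy()
    return x


def _isin(a, b):
    return np.isin(np.asarray(a, dtype=object), np.asarray(list(b), dtype=object))


class _Evaluator(ast.NodeVisitor):
    def __init__(self, resolve: Callable[[str], object]):
        self.resolve = resolve

    def visit_Expression(self, node):
        return self.visit(node.body)

    def visit_Name(self, node):
        return _as_array(self.resolve(node.id))

    def visit_Constant(self, node):
        return node.value

    def visit_List(self, node):
        return [self.visit(e) for e in node.elts]

    visit_Tuple = visit_List

    def visit_UnaryOp(self, node):
        operand = self.visit(node.operand)
        if isinstance(node.op, ast.Not):
            return ~np.asarray(operand, dtype=bool)
        if isinstance(node.op, ast.USub):
            return -operand
        raise ExpressionError(f"operator {type(node.op).__name__} not allowed")

    def visit_BoolOp(self, node):
        parts = [np.asarray(self.visit(v), dtype=bool) for v in node.values]
        combine = np.logical_and if isinstance(node.op, ast.And) else np.logical_or
        out = parts[0]
        for p in parts[1:]:
            out = combine(out, p)
        return out

    def visit_BinOp(self, node):
        fn = _BINOP.get(type(node.op))
        if fn is None:
            raise ExpressionError(f"operator {type(node.op).__name__} not allowed")
        return fn(self.visit(node.left), self.visit(node.right))

    def visit_Compare(self, node):
        left = self.visit(node.left)
        result = None
        for op, comparator in zip(node.ops, node.comparators):
            right = self.visit(comparator)
            if isinstance(op, ast.In):
                part = _isin(left, right)
            elif isinstance(op, ast.NotIn):
                part = ~_isin(left, right)
            else:
                fn = _CMP.get(type(op))
                if fn is None:
                    raise ExpressionError(f"comparison {type(op).__name__} not allowed")
                part = fn(left, right)
            part = np.asarray(part)
            result = part if result is None else np.logical_and(result, part)
            left = right
        return result

    def visit_Call(self, node):
        if not isinstance(node.func, ast.Name) or node.func.id not in _ALLOWED_FUNCS:
            raise ExpressionError(
                "only isna()/notna() calls are allowed in expressions"
            )
        if node.keywords or len(node.args) != 1:
            raise ExpressionError(f"{node.func.id}() takes exactly one argument")
        return _ALLOWED_FUNCS[node.func.id](self.visit(node.args[0]))

    def generic_visit(self, node):
        raise ExpressionError(
            f"syntax element {type(node).__name__} not allowed in expressions"
        )


def evaluate(expression: str, resolve: Callable[[str], object]):
    """Evaluate ``expression``, resolving bare names through ``resolve``.

    Returns a numpy array (or scalar for constant expressions).
    """
    try:
        tree = ast.parse(expression, mode="eval")
    except SyntaxError as exc:
        raise ExpressionError(f"cannot parse expression {expression!r}: {exc}") from exc
    return _Evaluator(resolve).visit(tree)
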