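"""Arithmetic rate expressions and boolean guard expressions.

Rates are small expression trees over real literals, parameter names,
``pop(State)`` (current occupancy of a state, summed over substates for a
compound) and ``ind(State)`` (1.0 when the product-state coordinate of that
state's region lies inside the state, else 0.0 — the hook for rates that
depend on the context in a parallel track). Guards are conjunctions of
``in(State)`` / ``not in(State)`` predicates over the other parallel tracks.

Both languages are deliberately tiny: anything the parser does not recognise
is rejected loudly rather than guessed at.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

__all__ = [
    "ExprError",
    "EvalError",
    "RateExpr",
    "GuardExpr",
    "Predicate",
    "parse_rate",
    "parse_guard",
    "TRUE_GUARD",
    "FUNCTIONS",
]


class ExprError(ValueError):
    """Raised for malformed expression text."""


class EvalError(ValueError):
    """Raised when evaluation hits an unresolvable symbol."""


#: Named functions callable from rate expressions.  ``hill(x, K) = x/(K+x)``
#: is the saturating form used for ligand-competition rates.
FUNCTIONS: dict[str, Callable[..., float]] = {
    "exp": math.exp,
    "log": math.log,
    "min": min,
    "max": max,
    "abs": abs,
    "hill": lambda x, k: x / (k + x),
}


# ---------------------------------------------------------------------------
# AST nodes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _Node:
    def evaluate(self, params, occupancy, coords_test) -> float:  # pragma: no cover
        raise NotImplementedError


@dataclass(frozen=True)
class _Num(_Node):
    value: float

    def evaluate(self, params, occupancy, coords_test):
        return self.value


@dataclass(frozen=True)
class _Param(_Node):
    name: str

    def evaluate(self, params, occupancy, coords_test):
        try:
            return float(params[self.name])
        except KeyError:
            raise EvalError(f"unresolved parameter {self.name!r}") from None


@dataclass(frozen=True)
class _Pop(_Node):
    state: str

    def evaluate(self, params, occupancy, coords_test):
        if occupancy is None:
            raise EvalError(f"pop({self.state}) needs an occupancy context")
        try:
            return float(occupancy(self.state))
        except KeyError:
            raise EvalError(f"pop() references unknown state {self.state!r}") from None


@dataclass(frozen=True)
class _Ind(_Node):
    state: str

    def evaluate(self, params, occupancy, coords_test):
        if coords_test is None:
            raise EvalError(f"ind({self.state}) needs a region-coordinate context")
        return 1.0 if coords_test(self.state) else 0.0


@dataclass(frozen=True)
class _Neg(_Node):
    operand: _Node

    def evaluate(self, params, occupancy, coords_test):
        return -self.operand.evaluate(params, occupancy, coords_test)


@dataclass(frozen=True)
class _BinOp(_Node):
    op: str
    left: _Node
    right: _Node

    def evaluate(self, params, occupancy, coords_test):
        a = self.left.evaluate(params, occupancy, coords_test)
        b = self.right.evaluate(params, occupancy, coords_test)
        if self.op == "+":
            return a + b
        if self.op == "-":
            return a - b
        if self.op == "*":
            return a * b
        return a / b


@dataclass(frozen=True)
class _Call(_Node):
    func: str
    args: tuple[_Node, ...]

    def evaluate(self, params, occupancy, coords_test):
        fn = FUNCTIONS.get(self.func)
        if fn is None:
            raise EvalError(f"unknown function {self.func!r}")
        return float(fn(*(a.evaluate(params, occupancy, coords_test) for a in self.args)))


# ---------------------------------------------------------------------------
# Tokenizer / recursive-descent parser
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<num>\d+\.?\d*(?:[eE][+-]?\d+)?|\.\d+(?:[eE][+-]?\d+)?)"
    r"|(?P<name>[A-Za-z_][A-Za-z0-9_]*)"
    r"|(?P<op>[-+*/(),]))"
)


def _tokenize(text: str) -> list[tuple[str, str]]:
    tokens: list[tuple[str, str]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            if text[pos:].strip():
                raise ExprError(f"unexpected character {text[pos:].strip()[0]!r} in {text!r}")
            break
        pos = m.end()
        for kind in ("num", "name", "op"):
            val = m.group(kind)
            if val is not None:
                tokens.append((kind, val))
                break
    tokens.append(("end", ""))
    return tokens


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0

    def peek(self) -> tuple[str, str]:
        return self.tokens[self.i]

    def next(self) -> tuple[str, str]:
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def expect(self, value: str) -> None:
        kind, val = self.next()
        if val != value:
            raise ExprError(f"expected {value!r}, found {val or 'end of input'!r} in {self.text!r}")

    def parse_expr(self) -> _Node:
        node = self.parse_term()
        while self.peek()[1] in ("+", "-"):
            op = self.next()[1]
            node = _BinOp(op, node, self.parse_term())
        return node

    def parse_term(self) -> _Node:
        node = self.parse_factor()
        while self.peek()[1] in ("*", "/"):
            op = self.next()[1]
            node = _BinOp(op, node, self.parse_factor())
        return node

    def parse_factor(self) -> _Node:
        kind, val = self.next()
        if val == "-":
            return _Neg(self.parse_factor())
        if val == "+":
            return self.parse_factor()
        if kind == "num":
            return _Num(float(val))
        if val == "(":
            node = self.parse_expr()
            self.expect(")")
            return node
        if kind == "name":
            if self.peek()[1] == "(":
                self.next()
                if val in ("pop", "ind"):
                    k, state = self.next()
                    if k != "name":
                        raise ExprError(f"{val}() takes a state name, got {state!r}")
                    self.expect(")")
                    return _Pop(state) if val == "pop" else _Ind(state)
                args: list[_Node] = []
                if self.peek()[1] != ")":
                    args.append(self.parse_expr())
                    while self.peek()[1] == ",":
                        self.next()
                        args.append(self.parse_expr())
                self.expect(")")
                if val not in FUNCTIONS:
                    raise ExprError(f"unknown function {val!r} in {self.text!r}")
                return _Call(val, tuple(args))
            return _Param(val)
        raise ExprError(f"unexpected {val or 'end of input'!r} in {self.text!r}")


# ---------------------------------------------------------------------------
# Public rate expression
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RateExpr:
    """A parsed arithmetic rate expression.

    Evaluation is total given a parameter table and (when ``pop``/``ind``
    appear) an occupancy lookup / coordinate predicate.
    """

    source: str
    root: _Node = field(compare=False, repr=False, default=None)  # type: ignore[assignment]

    def evaluate(
        self,
        params: Mapping[str, float],
        occupancy: Callable[[str], float] | Mapping[str, float] | None = None,
        coords_test: Callable[[str], bool] | None = None,
    ) -> float:
        lookup = occupancy
        if occupancy is not None and not callable(occupancy):
            lookup = occupancy.__getitem__
        return self.root.evaluate(params, lookup, coords_test)

    # -- introspection -----------------------------------------------------

    def _walk(self, node=None):
        node = self.root if node is None else node
        yield node
        if isinstance(node, _BinOp):
            yield from self._walk(node.left)
            yield from self._walk(node.right)
        elif isinstance(node, _Neg):
            yield from self._walk(node.operand)
        elif isinstance(node, _Call):
            for a in node.args:
                yield from self._walk(a)

    def param_refs(self) -> set[str]:
        return {n.name for n in self._walk() if isinstance(n, _Param)}

    def pop_refs(self) -> set[str]:
        return {n.state for n in self._walk() if isinstance(n, _Pop)}

    def ind_refs(self) -> set[str]:
        return {n.state for n in self._walk() if isinstance(n, _Ind)}

    def bind_coords(self, coords_test: Callable[[str], bool]) -> "RateExpr":
        """Substitute every ``ind(S)`` with its 0/1 value for fixed coordinates."""
        if not self.ind_refs():
            return self

        def sub(node):
            if isinstance(node, _Ind):
                return _Num(1.0 if coords_test(node.state) else 0.0)
            if isinstance(node, _BinOp):
                return _BinOp(node.op, sub(node.left), sub(node.right))
            if isinstance(node, _Neg):
                return _Neg(sub(node.operand))
            if isinstance(node, _Call):
                return _Call(node.func, tuple(sub(a) for a in node.args))
            return node

        return RateExpr(self.source, sub(self.root))

    def __str__(self) -> str:
        return self.source


def parse_rate(text: str | int | float) -> RateExpr:
    """Parse rate expression text (bare numbers are accepted for convenience)."""
    if isinstance(text, (int, float)):
        return RateExpr(repr(float(text)), _Num(float(text)))
    parser = _Parser(text)
    root = parser.parse_expr()
    if parser.peek()[0] != "end":
        raise ExprError(f"trailing input {parser.peek()[1]!r} in {text!r}")
    return RateExpr(text, root)


# ---------------------------------------------------------------------------
# Guards
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Predicate:
    state: str
    negated: bool

    def __str__(self) -> str:
        return ("not in(%s)" if self.negated else "in(%s)") % self.state


@dataclass(frozen=True)
class GuardExpr:
    """Conjunction of ``in``/``not in`` predicates; empty conjunction is TRUE."""

    predicates: tuple[Predicate, ...] = ()

    def is_true(self) -> bool:
        return not self.predicates

    def evaluate(self, in_state: Callable[[str], bool]) -> bool:
        """``in_state(S)`` must report whether the active coordinate of S's
        region is S or one of its descendants."""
        for p in self.predicates:
            held = in_state(p.state)
            if held == p.negated:
                return False
        return True

    def state_refs(self) -> set[str]:
        return {p.state for p in self.predicates}

    def __str__(self) -> str:
        return " and ".join(str(p) for p in self.predicates)


TRUE_GUARD = GuardExpr()

_GUARD_PRED_RE = re.compile(
    r"^\s*(?P<neg>not\s+)?in\s*\(\s*(?P<state>[A-Za-z_][A-Za-z0-9_]*)\s*\)\s*$"
)


def parse_guard(text: str | None) -> GuardExpr:
    """Parse ``"in(X) and not in(Y)"``; ``None``/empty → TRUE.

    Only conjunctions of in/not-in predicates are accepted: richer boolean
    logic is rejected rather than silently misread.
    """
    if text is None or not text.strip():
        return TRUE_GUARD
    preds = []
    for part in re.split(r"\band\b", text):
        m = _GUARD_PRED_RE.match(part)
        if m is None:
            raise ExprError(
                f"guard clause {part.strip()!r} is not of the form 'in(State)' / 'not in(State)'"
            )
        preds.append(Predicate(m.group("state"), bool(m.group("neg"))))
    return GuardExpr(tuple(preds))
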