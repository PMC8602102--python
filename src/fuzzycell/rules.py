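"""Rule language for logical regulatory networks.

A network is declared in a small plain-text format, one update rule per
line::

    # comment
    input CD8086
    CD28   = CD8086 and not CTLA4
    MTORC1 = MTOR and not AMPK

Expressions combine node identifiers with ``and``/``&``, ``or``/``|``,
``not``/``!`` and parentheses.  Precedence is ``not`` > ``and`` > ``or``.
Identifiers match ``[A-Za-z0-9_]+``; ``input NAME`` declares an externally
driven node that carries no rule.

Every rule is an expression tree (:class:`Var`, :class:`Not`, :class:`And`,
:class:`Or`) that can be evaluated under two semantics:

* Boolean -- the classical connectives on {0, 1};
* fuzzy   -- the product / probabilistic-sum / complement algebra
  (``q and p -> q*p``, ``q or p -> q + p - q*p``, ``not p -> 1 - p``),
  which maps [0,1]^n into [0,1] and agrees with the Boolean semantics on
  every corner assignment.

The fuzzy algebra is applied per occurrence: a variable repeated inside one
rule is multiplied in as many times as it appears (no idempotence
correction), which is exactly what the algebraic translation prescribes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

__all__ = [
    "RuleError",
    "Expr",
    "Var",
    "Not",
    "And",
    "Or",
    "Node",
    "NetworkModel",
    "parse_expr",
    "parse_rules",
    "serialize_rules",
    "eval_boolean",
    "eval_fuzzy",
    "interaction_table",
]


class RuleError(ValueError):
    """Syntax or semantic error in a rule file."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


# ---------------------------------------------------------------------------
# Expression trees
# ---------------------------------------------------------------------------


class Expr:
    """Base class for rule expression trees."""

    def eval_boolean(self, state: Mapping[str, int]) -> int:
        raise NotImplementedError

    def eval_fuzzy(self, state: Mapping[str, float]) -> float:
        raise NotImplementedError

    def variables(self) -> set[str]:
        return set(self._vars())

    def _vars(self) -> Iterator[str]:
        raise NotImplementedError

    def signed_vars(self, negated: bool = False) -> Iterator[tuple[str, bool]]:
        """Yield ``(name, negated)`` for every variable occurrence."""
        raise NotImplementedError

    def to_text(self, parent_prec: int = 0) -> str:
        raise NotImplementedError

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_text()

    def __eq__(self, other) -> bool:
        return type(self) is type(other) and self._key() == other._key()

    def __hash__(self) -> int:
        return hash((type(self).__name__, self._key()))

    def _key(self):
        raise NotImplementedError


@dataclass(frozen=True, eq=False)
class Var(Expr):
    name: str

    def eval_boolean(self, state):
        try:
            v = state[self.name]
        except KeyError:
            raise RuleError(f"variable {self.name!r} missing from state") from None
        if v not in (0, 1):
            raise RuleError(f"Boolean state for {self.name!r} must be 0 or 1, got {v!r}")
        return int(v)

    def eval_fuzzy(self, state):
        try:
            v = state[self.name]
        except KeyError:
            raise RuleError(f"variable {self.name!r} missing from state") from None
        if not (0.0 <= v <= 1.0):
            raise RuleError(f"fuzzy level for {self.name!r} outside [0, 1]: {v!r}")
        return float(v)

    def _vars(self):
        yield self.name

    def signed_vars(self, negated=False):
        yield (self.name, negated)

    def to_text(self, parent_prec=0):
        return self.name

    def _key(self):
        return self.name


@dataclass(frozen=True, eq=False)
class Not(Expr):
    child: Expr

    PREC = 3

    def eval_boolean(self, state):
        return 1 - self.child.eval_boolean(state)

    def eval_fuzzy(self, state):
        return 1.0 - self.child.eval_fuzzy(state)

    def _vars(self):
        yield from self.child._vars()

    def signed_vars(self, negated=False):
        yield from self.child.signed_vars(not negated)

    def to_text(self, parent_prec=0):
        inner = self.child.to_text(self.PREC)
        return f"not {inner}"

    def _key(self):
        return self.child


class _Nary(Expr):
    OP = ""
    PREC = 0

    def __init__(self, children: Iterable[Expr]):
        # flatten nested same-type connectives: both fuzzy operators are
        # associative, so (a ∘ b) ∘ c and a ∘ b ∘ c are the same expression
        flat: list[Expr] = []
        for c in children:
            if type(c) is type(self):
                flat.extend(c.children)
            else:
                flat.append(c)
        if len(flat) < 2:
            raise ValueError(f"{type(self).__name__} needs at least two children")
        self.children = tuple(flat)

    def _vars(self):
        for c in self.children:
            yield from c._vars()

    def signed_vars(self, negated=False):
        for c in self.children:
            yield from c.signed_vars(negated)

    def to_text(self, parent_prec=0):
        body = f" {self.OP} ".join(c.to_text(self.PREC) for c in self.children)
        if parent_prec > self.PREC:
            return f"({body})"
        return body

    def _key(self):
        return self.children

    def __repr__(self):  # pragma: no cover
        return f"{type(self).__name__}({list(self.children)!r})"


class And(_Nary):
    OP = "and"
    PREC = 2

    def eval_boolean(self, state):
        out = 1
        for c in self.children:
            out &= c.eval_boolean(state)
        return out

    def eval_fuzzy(self, state):
        out = 1.0
        for c in self.children:
            out *= c.eval_fuzzy(state)
        return out


class Or(_Nary):
    OP = "or"
    PREC = 1

    def eval_boolean(self, state):
        out = 0
        for c in self.children:
            out |= c.eval_boolean(state)
        return out

    def eval_fuzzy(self, state):
        # probabilistic sum: a + b - a*b, folded left
        out = 0.0
        for c in self.children:
            v = c.eval_fuzzy(state)
            out = out + v - out * v
        return out


def eval_boolean(rule: Expr, state: Mapping[str, int]) -> int:
    """Evaluate *rule* under classical Boolean semantics."""
    return rule.eval_boolean(state)


def eval_fuzzy(rule: Expr, state: Mapping[str, float]) -> float:
    """Evaluate *rule* under the product/probabilistic-sum fuzzy algebra."""
    return rule.eval_fuzzy(state)


# ---------------------------------------------------------------------------
# Parser
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"""
    (?P<ws>\s+)
  | (?P<lpar>\()
  | (?P<rpar>\))
  | (?P<amp>&)
  | (?P<pipe>\|)
  | (?P<bang>!)
  | (?P<ident>[A-Za-z0-9_]+)
    """,
    re.VERBOSE,
)

_KEYWORDS = {"and", "or", "not", "input"}


def _tokenize(text: str, line: int) -> list[tuple[str, str]]:
    tokens: list[tuple[str, str]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            raise RuleError(f"unexpected character {text[pos]!r}", line)
        pos = m.end()
        kind = m.lastgroup
        if kind == "ws":
            continue
        value = m.group()
        if kind == "ident":
            low = value.lower()
            if low in ("and", "or", "not"):
                tokens.append((low, value))
            else:
                tokens.append(("ident", value))
        elif kind == "amp":
            tokens.append(("and", value))
        elif kind == "pipe":
            tokens.append(("or", value))
        elif kind == "bang":
            tokens.append(("not", value))
        else:
            tokens.append((kind, value))
    return tokens


class _Parser:
    def __init__(self, tokens: list[tuple[str, str]], line: int):
        self.tokens = tokens
        self.pos = 0
        self.line = line

    def peek(self) -> str | None:
        return self.tokens[self.pos][0] if self.pos < len(self.tokens) else None

    def take(self) -> tuple[str, str]:
        if self.pos >= len(self.tokens):
            raise RuleError("unexpected end of expression", self.line)
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def expect(self, kind: str) -> str:
        k, v = self.take()
        if k != kind:
            raise RuleError(f"expected {kind!r}, found {v!r}", self.line)
        return v

    def parse(self) -> Expr:
        expr = self.disjunction()
        if self.pos != len(self.tokens):
            raise RuleError(
                f"trailing input {self.tokens[self.pos][1]!r}", self.line
            )
        return expr

    def disjunction(self) -> Expr:
        terms = [self.conjunction()]
        while self.peek() == "or":
            self.take()
            terms.append(self.conjunction())
        return terms[0] if len(terms) == 1 else Or(terms)

    def conjunction(self) -> Expr:
        factors = [self.factor()]
        while self.peek() == "and":
            self.take()
            factors.append(self.factor())
        return factors[0] if len(factors) == 1 else And(factors)

    def factor(self) -> Expr:
        kind = self.peek()
        if kind == "not":
            self.take()
            return Not(self.factor())
        if kind == "lpar":
            self.take()
            expr = self.disjunction()
            self.expect("rpar")
            return expr
        if kind == "ident":
            return Var(self.take()[1])
        _, v = self.take()
        raise RuleError(f"unexpected token {v!r}", self.line)


def parse_expr(text: str, line: int = 1) -> Expr:
    """Parse a single expression (right-hand side of a rule)."""
    tokens = _tokenize(text, line)
    if not tokens:
        raise RuleError("empty expression", line)
    return _Parser(tokens, line).parse()


# ---------------------------------------------------------------------------
# Network model
# ---------------------------------------------------------------------------


@dataclass
class Node:
    """One network component.

    ``decay`` is the first-order decay rate d_k of the continuous dynamics
    (characteristic expression time tau_k = 1/d_k); ``initial`` the level
    q_k(0).  Input nodes carry no rule and are driven externally.
    """

    name: str
    rule: Expr | None = None
    decay: float = 1.0
    initial: float = 0.0
    is_input: bool = False

    def __post_init__(self):
        if self.decay <= 0:
            raise ValueError(f"node {self.name}: decay rate must be positive")
        if self.initial < 0:
            raise ValueError(f"node {self.name}: initial level must be >= 0")
        if self.is_input and self.rule is not None:
            raise ValueError(f"node {self.name}: input nodes cannot carry a rule")


@dataclass
class NetworkModel:
    """A named collection of nodes with update rules and global parameters.

    ``beta`` is the gain of the sigmoid membership function and ``w_thr``
    its activation threshold (see :mod:`fuzzycell.continuous`).
    ``display_names`` maps identifiers to presentation names (e.g.
    ``AMP_ATP -> "AMP/ATP"``; the slash cannot appear in an identifier).
    """

    nodes: dict[str, Node] = field(default_factory=dict)
    beta: float = 5.0
    w_thr: float = 0.5
    display_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if not (0.0 < self.w_thr < 1.0):
            raise ValueError("w_thr must lie in (0, 1)")
        self.validate()

    # -- introspection ----------------------------------------------------
    @property
    def names(self) -> list[str]:
        return list(self.nodes)

    @property
    def input_names(self) -> list[str]:
        return [n for n, node in self.nodes.items() if node.is_input]

    @property
    def free_names(self) -> list[str]:
        return [n for n, node in self.nodes.items() if not node.is_input]

    def display(self, name: str) -> str:
        return self.display_names.get(name, name)

    def validate(self) -> None:
        for node in self.nodes.values():
            if node.rule is None:
                continue
            for ref in node.rule.variables():
                if ref not in self.nodes:
                    raise RuleError(
                        f"rule for {node.name!r} references undeclared name {ref!r}"
                    )

    # -- mutation helpers -------------------------------------------------
    def set_decay(self, name: str, decay: float) -> None:
        if name not in self.nodes:
            raise KeyError(name)
        if decay <= 0:
            raise ValueError("decay rate must be positive")
        self.nodes[name].decay = decay

    def set_initial(self, name: str, level: float) -> None:
        if name not in self.nodes:
            raise KeyError(name)
        self.nodes[name].initial = float(level)

    def copy(self) -> "NetworkModel":
        nodes = {
            n.name: Node(n.name, n.rule, n.decay, n.initial, n.is_input)
            for n in self.nodes.values()
        }
        return NetworkModel(
            nodes, self.beta, self.w_thr, dict(self.display_names)
        )


_NAME_RE = re.compile(r"^[A-Za-z0-9_]+$")


def parse_rules(
    text: str,
    beta: float = 5.0,
    w_thr: float = 0.5,
    display_names: Mapping[str, str] | None = None,
) -> NetworkModel:
    """Parse a rule file into a :class:`NetworkModel`.

    Raises :class:`RuleError` (with line number) on syntax errors,
    duplicate definitions, or references to undeclared names.
    """
    nodes: dict[str, Node] = {}
    order_rules: list[tuple[int, str, str]] = []

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        m = re.match(r"^input\s+(.+)$", line, re.IGNORECASE)
        if m and "=" not in line:
            name = m.group(1).strip()
            if not _NAME_RE.match(name):
                raise RuleError(f"invalid input name {name!r}", lineno)
            if name in nodes:
                raise RuleError(f"duplicate definition of {name!r}", lineno)
            nodes[name] = Node(name, None, is_input=True)
            continue
        if "=" not in line:
            raise RuleError("expected 'NAME = EXPR' or 'input NAME'", lineno)
        lhs, rhs = line.split("=", 1)
        name = lhs.strip()
        if not _NAME_RE.match(name):
            raise RuleError(f"invalid node name {name!r}", lineno)
        if name.lower() in _KEYWORDS:
            raise RuleError(f"node name {name!r} is a reserved word", lineno)
        if name in nodes:
            raise RuleError(f"duplicate definition of {name!r}", lineno)
        nodes[name] = Node(name, parse_expr(rhs, lineno))
        order_rules.append((lineno, name, rhs))

    model = NetworkModel(
        nodes, beta=beta, w_thr=w_thr,
        display_names=dict(display_names or {}),
    )
    return model


def serialize_rules(model: NetworkModel) -> str:
    """Render a model back to rule-file text (inverse of :func:`parse_rules`)."""
    lines = []
    for node in model.nodes.values():
        if node.is_input:
            lines.append(f"input {node.name}")
        else:
            lines.append(f"{node.name} = {node.rule.to_text()}")
    return "\n".join(lines) + "\n"


def interaction_table(model: NetworkModel) -> list[tuple[str, str, str]]:
    """Signed interaction edges derived from rule syntax.

    Returns ``(source, target, sign)`` rows, sign ``+`` for an un-negated
    occurrence and ``-`` for a negated one.  A variable appearing with both
    parities contributes two rows.
    """
    rows: list[tuple[str, str, str]] = []
    seen: set[tuple[str, str, str]] = set()
    for node in model.nodes.values():
        if node.rule is None:
            continue
        for source, negated in node.rule.signed_vars():
            row = (source, node.name, "-" if negated else "+")
            if row not in seen:
                seen.add(row)
                rows.append(row)
    return rows
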