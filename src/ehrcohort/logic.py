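"""Boolean exposure-combination grammar and its evaluators.

Grammar (a regular-style grammar handled by a hand-written recursive-descent
parser)::

    expr   := term ("or" term)*
    term   := factor ("and" factor)*
    factor := NAME | "(" expr ")"

``and`` binds tighter than ``or``; keywords are case-insensitive; NAME is an
identifier referring to a declared inclusion code entity. There is no NOT:
negative criteria are expressed through exclusion code entities.

Two evaluation modes map an expression plus a per-entity earliest-event date
to a patient index date:

* **loose** — order-free. An ``and`` is satisfied when both sides are and
  contributes the later of the two dates ("latest event date among the code
  entities"); an ``or`` contributes the earliest date on which either branch
  was satisfied. Equivalently: the earliest date on which the whole
  expression first became true.
* **strict** — within every ``and`` chain the entities must have occurred in
  the written order (left date <= right date, same-day counts as in-order);
  ``or`` branches are alternatives. A patient satisfying the boolean shape
  only out of order is *rejected* rather than merely unsatisfied.

Strict evaluation is implemented as a candidate-set recursion: every node
yields the set of achievable in-order "completion dates" over resolutions of
its ``or`` nodes; the result is the earliest candidate. This is required for
correctness when the earliest branch of an ``or`` breaks a downstream order
constraint that another branch would satisfy.
"""
from __future__ import annotations

import datetime as dt
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Union

# --------------------------------------------------------------------------
# AST
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class EntityRef:
    name: str


@dataclass(frozen=True)
class And:
    left: "Node"
    right: "Node"


@dataclass(frozen=True)
class Or:
    left: "Node"
    right: "Node"


Node = Union[EntityRef, And, Or]


def entity_names(node: Node) -> set[str]:
    if isinstance(node, EntityRef):
        return {node.name}
    return entity_names(node.left) | entity_names(node.right)


def to_text(node: Node) -> str:
    """Canonical textual form (lowercase keywords, parentheses only where
    precedence requires them). ``parse(to_text(ast)) == ast``."""
    if isinstance(node, EntityRef):
        return node.name
    if isinstance(node, And):
        left = to_text(node.left)
        right = to_text(node.right)
        if isinstance(node.left, Or):
            left = f"({left})"
        if isinstance(node.right, (Or, And)):  # parsing is left-associative
            right = f"({right})"
        return f"{left} and {right}"
    left = to_text(node.left)
    right = to_text(node.right)
    if isinstance(node.right, Or):
        right = f"({right})"
    return f"{left} or {right}"


# --------------------------------------------------------------------------
# Parsing
# --------------------------------------------------------------------------


class LogicParseError(ValueError):
    def __init__(self, message: str, position: int) -> None:
        super().__init__(f"{message} (at position {position})")
        self.position = position


class LogicReferenceError(ValueError):
    def __init__(self, names: Iterable[str]) -> None:
        self.names = sorted(names)
        super().__init__(f"undeclared code entities referenced: {', '.join(self.names)}")


_TOKEN = re.compile(r"\s*(?:(?P<lpar>\()|(?P<rpar>\))|(?P<name>[A-Za-z_][A-Za-z0-9_.]*))")


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens: list[tuple[str, str, int]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None:
            stripped = text[pos:].lstrip()
            if not stripped:
                break
            raise LogicParseError(f"unexpected character {stripped[0]!r}",
                                  len(text) - len(stripped))
        if m.lastgroup == "name":
            word = m.group("name")
            kind = word.lower() if word.lower() in ("and", "or") else "name"
            tokens.append((kind, word, m.start("name")))
        elif m.lastgroup == "lpar":
            tokens.append(("(", "(", m.start("lpar")))
        else:
            tokens.append((")", ")", m.start("rpar")))
        pos = m.end()
    tokens.append(("eof", "", len(text)))
    return tokens


class _Parser:
    def __init__(self, text: str) -> None:
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0

    def peek(self) -> tuple[str, str, int]:
        return self.tokens[self.i]

    def next(self) -> tuple[str, str, int]:
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def parse(self) -> Node:
        node = self.expr()
        kind, val, pos = self.peek()
        if kind != "eof":
            raise LogicParseError(f"unexpected token {val!r}", pos)
        return node

    def expr(self) -> Node:
        node = self.term()
        while self.peek()[0] == "or":
            self.next()
            node = Or(node, self.term())
        return node

    def term(self) -> Node:
        node = self.factor()
        while self.peek()[0] == "and":
            self.next()
            node = And(node, self.factor())
        return node

    def factor(self) -> Node:
        kind, val, pos = self.next()
        if kind == "name":
            return EntityRef(val)
        if kind == "(":
            node = self.expr()
            kind2, val2, pos2 = self.next()
            if kind2 != ")":
                raise LogicParseError("expected ')'", pos2)
            return node
        if kind == "eof":
            raise LogicParseError("unexpected end of expression", pos)
        raise LogicParseError(f"unexpected token {val!r}", pos)


def parse_logic(expression_text: str, declared_entities: Optional[Iterable[str]] = None) -> Node:
    """Parse an expression; optionally verify every NAME is declared."""
    if not expression_text or not expression_text.strip():
        raise LogicParseError("empty expression", 0)
    ast = _Parser(expression_text).parse()
    if declared_entities is not None:
        unknown = entity_names(ast) - set(declared_entities)
        if unknown:
            raise LogicReferenceError(unknown)
    return ast


# --------------------------------------------------------------------------
# Evaluation
# --------------------------------------------------------------------------

DateMap = Mapping[str, Optional[dt.date]]


def evaluate_loose(ast: Node, entity_index_dates: DateMap) -> Optional[dt.date]:
    """Earliest date on which the expression becomes true, else ``None``."""
    if isinstance(ast, EntityRef):
        return entity_index_dates[ast.name]
    left = evaluate_loose(ast.left, entity_index_dates)
    right = evaluate_loose(ast.right, entity_index_dates)
    if isinstance(ast, And):
        if left is None or right is None:
            return None
        return max(left, right)
    if left is None:
        return right
    if right is None:
        return left
    return min(left, right)


@dataclass(frozen=True)
class StrictResult:
    status: str  # "date" | "reject_order" | "unsatisfied"
    date: Optional[dt.date] = None

    REJECT_ORDER = "reject_order"
    UNSATISFIED = "unsatisfied"
    DATE = "date"


def _strict_candidates(ast: Node, dates: DateMap) -> set[dt.date]:
    """Set of completion dates achievable by in-order resolutions of the
    expression's ``or`` choices."""
    if isinstance(ast, EntityRef):
        d = dates[ast.name]
        return set() if d is None else {d}
    left = _strict_candidates(ast.left, dates)
    right = _strict_candidates(ast.right, dates)
    if isinstance(ast, Or):
        return left | right
    return {b for a in left for b in right if a <= b}


def evaluate_strict(ast: Node, entity_index_dates: DateMap) -> StrictResult:
    """Order-sensitive evaluation.

    Returns the earliest in-order completion date; ``reject_order`` when the
    boolean shape is satisfiable from the present entities but only out of
    the written order; ``unsatisfied`` otherwise.
    """
    candidates = _strict_candidates(ast, entity_index_dates)
    if candidates:
        return StrictResult(StrictResult.DATE, min(candidates))
    if evaluate_loose(ast, entity_index_dates) is not None:
        return StrictResult(StrictResult.REJECT_ORDER)
    return StrictResult(StrictResult.UNSATISFIED)
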