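"""Boolean rule expressions: grammar, parsing, evaluation.

A rule is a Boolean expression over node names with ``!`` (NOT, highest
precedence), ``&`` (AND), ``|`` (OR, lowest precedence), parentheses, and the
constant literals ``0``/``1``.  Identifiers are ``[A-Za-z_][A-Za-z0-9_]*``.

The expression tree prints back to a canonical string that re-parses to the
identical tree, which is what makes the plain-text model format round-trip.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Mapping, Tuple

__all__ = [
    "Expr",
    "Var",
    "Not",
    "And",
    "Or",
    "Const",
    "LogicRule",
    "RuleSyntaxError",
    "parse_rule",
    "evaluate_rule",
]


class RuleSyntaxError(ValueError):
    """Malformed rule text; carries the character position of the problem."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


# ---------------------------------------------------------------------------
# Expression tree
# ---------------------------------------------------------------------------

class Expr:
    """Base class for Boolean expression nodes."""

    #: precedence for printing: OR=1, AND=2, NOT=3, atoms=4
    _prec = 4

    def evaluate(self, state: Mapping[str, int]) -> int:
        raise NotImplementedError

    def variables(self) -> Iterator[str]:
        """Yield referenced names in order of appearance (with repeats)."""
        raise NotImplementedError

    def _fmt(self, parent_prec: int) -> str:
        s = str(self)
        if self._prec < parent_prec:
            return f"({s})"
        return s


@dataclass(frozen=True)
class Var(Expr):
    name: str
    _prec = 4

    def evaluate(self, state):
        try:
            v = state[self.name]
        except KeyError:
            raise KeyError(f"state missing regulator {self.name!r}") from None
        return 1 if v else 0

    def variables(self):
        yield self.name

    def __str__(self):
        return self.name


@dataclass(frozen=True)
class Const(Expr):
    value: int
    _prec = 4

    def evaluate(self, state):
        return self.value

    def variables(self):
        return iter(())

    def __str__(self):
        return str(self.value)


@dataclass(frozen=True)
class Not(Expr):
    child: Expr
    _prec = 3

    def evaluate(self, state):
        return 1 - self.child.evaluate(state)

    def variables(self):
        yield from self.child.variables()

    def __str__(self):
        return "!" + self.child._fmt(self._prec + 1)


@dataclass(frozen=True)
class And(Expr):
    left: Expr
    right: Expr
    _prec = 2

    def evaluate(self, state):
        return self.left.evaluate(state) & self.right.evaluate(state)

    def variables(self):
        yield from self.left.variables()
        yield from self.right.variables()

    def __str__(self):
        # right child parenthesized at equal precedence: canonical form is
        # left-associative, so printing re-parses to the identical tree
        return f"{self.left._fmt(self._prec)} & {self.right._fmt(self._prec + 1)}"


@dataclass(frozen=True)
class Or(Expr):
    left: Expr
    right: Expr
    _prec = 1

    def evaluate(self, state):
        return self.left.evaluate(state) | self.right.evaluate(state)

    def variables(self):
        yield from self.left.variables()
        yield from self.right.variables()

    def __str__(self):
        return f"{self.left._fmt(self._prec)} | {self.right._fmt(self._prec + 1)}"


# ---------------------------------------------------------------------------
# Tokenizer / recursive-descent parser
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\s*(?:(?P<ident>[A-Za-z_][A-Za-z0-9_]*)"
                       r"|(?P<const>[01])"
                       r"|(?P<op>[!&|()]))")


def _tokenize(text: str) -> List[Tuple[str, str, int]]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            if text[pos:].strip() == "":
                break
            bad = len(text) - len(text[pos:].lstrip())
            raise RuleSyntaxError(f"unexpected character {text[bad]!r}", bad)
        if m.group("ident"):
            tokens.append(("ident", m.group("ident"), m.start("ident")))
        elif m.group("const"):
            tokens.append(("const", m.group("const"), m.start("const")))
        else:
            tokens.append(("op", m.group("op"), m.start("op")))
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0

    def _peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def _next(self):
        tok = self._peek()
        if tok is None:
            raise RuleSyntaxError("unexpected end of expression", len(self.text))
        self.i += 1
        return tok

    def parse(self) -> Expr:
        if not self.tokens:
            raise RuleSyntaxError("empty expression", 0)
        expr = self._or()
        tok = self._peek()
        if tok is not None:
            raise RuleSyntaxError(f"unexpected token {tok[1]!r}", tok[2])
        return expr

    def _or(self) -> Expr:
        node = self._and()
        while (tok := self._peek()) is not None and tok[1] == "|":
            self._next()
            node = Or(node, self._and())
        return node

    def _and(self) -> Expr:
        node = self._factor()
        while (tok := self._peek()) is not None and tok[1] == "&":
            self._next()
            node = And(node, self._factor())
        return node

    def _factor(self) -> Expr:
        kind, value, pos = self._next()
        if kind == "ident":
            return Var(value)
        if kind == "const":
            return Const(int(value))
        if value == "!":
            return Not(self._factor())
        if value == "(":
            node = self._or()
            tok = self._peek()
            if tok is None or tok[1] != ")":
                raise RuleSyntaxError("unbalanced parenthesis",
                                      tok[2] if tok else len(self.text))
            self._next()
            return node
        raise RuleSyntaxError(f"unexpected token {value!r}", pos)


# ---------------------------------------------------------------------------
# LogicRule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LogicRule:
    """A Boolean update rule: expression tree plus its ordered regulators.

    ``regulators`` is derived: the distinct names referenced by the
    expression, in order of first appearance.
    """

    expression: Expr
    regulators: Tuple[str, ...] = field(init=False)

    def __post_init__(self):
        seen: Dict[str, None] = {}
        for name in self.expression.variables():
            seen.setdefault(name)
        object.__setattr__(self, "regulators", tuple(seen))

    def evaluate(self, state: Mapping[str, int]) -> int:
        return self.expression.evaluate(state)

    def truth_table(self):
        """Output for every regulator assignment, regulator 0 as LSB.

        Returns a numpy uint8 array of length ``2**k`` where entry ``i``
        is the rule value with regulator ``j`` set to bit ``j`` of ``i``.
        """
        import numpy as np

        k = len(self.regulators)
        out = np.empty(2 ** k, dtype=np.uint8)
        for i in range(2 ** k):
            state = {r: (i >> j) & 1 for j, r in enumerate(self.regulators)}
            out[i] = self.expression.evaluate(state)
        return out

    def __str__(self):
        return str(self.expression)


def parse_rule(text: str) -> LogicRule:
    """Parse rule text into a :class:`LogicRule`.

    Raises :class:`RuleSyntaxError` (with position) on malformed input.
    """
    if text is None or text.strip() == "":
        raise RuleSyntaxError("empty expression", 0)
    return LogicRule(_Parser(text).parse())


def evaluate_rule(rule: LogicRule, state: Mapping[str, int]) -> int:
    """Evaluate ``rule`` on a complete 0/1 assignment of its regulators."""
    return rule.evaluate(state)
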