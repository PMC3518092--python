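"""Gene-protein-reaction (GPR) boolean rules.

A GPR rule links a reaction to the genes whose products catalyse it:
``and`` encodes an enzyme complex (every subunit required), ``or`` encodes
isozymes (any one suffices).  A reaction is disabled by a gene deletion
exactly when its rule evaluates to False with the deleted genes set False
and every other gene True.

Grammar: infix ``and`` / ``or`` with parentheses, case-insensitive
keywords; gene identifiers are runs of letters, digits, ``_``, ``.``, ``-``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator


class GprParseError(ValueError):
    """Raised when a GPR string cannot be parsed."""


@dataclass(frozen=True)
class Gene:
    """Leaf node: a single gene identifier."""

    id: str

    def evaluate(self, deleted: frozenset[str] | set[str]) -> bool:
        return self.id not in deleted

    def genes(self) -> set[str]:
        return {self.id}

    def to_string(self) -> str:
        return self.id


@dataclass(frozen=True)
class BoolOp:
    """Internal node: ``and`` (complex) or ``or`` (isozymes) over children."""

    op: str  # "and" | "or"
    args: tuple["GprExpression", ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.op not in ("and", "or"):
            raise ValueError(f"unknown GPR operator {self.op!r}")
        if len(self.args) < 2:
            raise ValueError("BoolOp requires at least two operands")

    def evaluate(self, deleted: frozenset[str] | set[str]) -> bool:
        values = (a.evaluate(deleted) for a in self.args)
        return all(values) if self.op == "and" else any(values)

    def genes(self) -> set[str]:
        out: set[str] = set()
        for a in self.args:
            out |= a.genes()
        return out

    def to_string(self) -> str:
        parts = []
        for a in self.args:
            s = a.to_string()
            if isinstance(a, BoolOp) and a.op != self.op:
                s = f"({s})"
            parts.append(s)
        return f" {self.op} ".join(parts)


GprExpression = Gene | BoolOp

_TOKEN_RE = re.compile(r"\(|\)|[A-Za-z0-9_.\-]+")


def _tokenize(text: str) -> Iterator[str]:
    pos = 0
    for m in _TOKEN_RE.finditer(text):
        if text[pos : m.start()].strip():
            raise GprParseError(f"unexpected characters in GPR: {text[pos:m.start()]!r}")
        pos = m.end()
        yield m.group(0)
    if text[pos:].strip():
        raise GprParseError(f"unexpected characters in GPR: {text[pos:]!r}")


def parse_gpr(text: str | None) -> GprExpression | None:
    """Parse a GPR string into an expression tree.

    Returns None for empty/blank input. ``or`` binds looser than ``and``,
    matching the usual boolean convention.
    """
    if text is None or not text.strip():
        return None
    tokens = list(_tokenize(text))
    expr, rest = _parse_or(tokens, 0)
    if rest != len(tokens):
        raise GprParseError(f"trailing tokens in GPR: {tokens[rest:]}")
    return expr


def _parse_or(tokens: list[str], i: int) -> tuple[GprExpression, int]:
    left, i = _parse_and(tokens, i)
    args = [left]
    while i < len(tokens) and tokens[i].lower() == "or":
        nxt, i = _parse_and(tokens, i + 1)
        args.append(nxt)
    return (args[0] if len(args) == 1 else BoolOp("or", tuple(args))), i


def _parse_and(tokens: list[str], i: int) -> tuple[GprExpression, int]:
    left, i = _parse_atom(tokens, i)
    args = [left]
    while i < len(tokens) and tokens[i].lower() == "and":
        nxt, i = _parse_atom(tokens, i + 1)
        args.append(nxt)
    return (args[0] if len(args) == 1 else BoolOp("and", tuple(args))), i


def _parse_atom(tokens: list[str], i: int) -> tuple[GprExpression, int]:
    if i >= len(tokens):
        raise GprParseError("unexpected end of GPR expression")
    tok = tokens[i]
    if tok == "(":
        expr, i = _parse_or(tokens, i + 1)
        if i >= len(tokens) or tokens[i] != ")":
            raise GprParseError("unbalanced parentheses in GPR")
        return expr, i + 1
    if tok == ")" or tok.lower() in ("and", "or"):
        raise GprParseError(f"unexpected token {tok!r} in GPR")
    return Gene(tok), i + 1


def evaluate_gpr(expr: GprExpression | None, deleted: set[str]) -> bool:
    """Truth value of a rule with ``deleted`` genes knocked out.

    A reaction with no rule (None) is never disabled by gene deletion.
    """
    if expr is None:
        return True
    return expr.evaluate(frozenset(deleted))
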