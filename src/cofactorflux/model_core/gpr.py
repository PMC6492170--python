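"""Boolean gene-protein-reaction (GPR) rules.

AND encodes a protein complex (all subunits required), OR encodes
isoenzymes (any one gene suffices). ``and`` binds tighter than ``or``,
matching the convention used by COBRA-style model files.
"""

from __future__ import annotations

import re
from abc import ABC, abstractmethod
from typing import Iterable, Set

__all__ = ["GPR", "Gene", "And", "Or", "parse_gpr", "gpr_and"]

_TOKEN = re.compile(r"\(|\)|[^\s()]+")


class GPR(ABC):
    """Node of a boolean expression tree over gene identifiers."""

    @abstractmethod
    def evaluate(self, knocked_out: Set[str]) -> bool:
        """Truth value when every gene in *knocked_out* is absent."""

    @abstractmethod
    def genes(self) -> Set[str]:
        """All gene identifiers mentioned in the expression."""

    @abstractmethod
    def to_string(self) -> str:
        """Canonical parenthesised text form."""

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"{type(self).__name__}({self.to_string()!r})"

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GPR) and self.to_string() == other.to_string()

    def __hash__(self) -> int:
        return hash(self.to_string())


class Gene(GPR):
    def __init__(self, name: str):
        if not name:
            raise ValueError("gene identifier must be non-empty")
        self.name = name

    def evaluate(self, knocked_out: Set[str]) -> bool:
        return self.name not in knocked_out

    def genes(self) -> Set[str]:
        return {self.name}

    def to_string(self) -> str:
        return self.name


class _NAry(GPR):
    op = ""

    def __init__(self, children: Iterable[GPR]):
        self.children = list(children)
        if len(self.children) < 1:
            raise ValueError(f"{type(self).__name__} needs at least one child")

    def genes(self) -> Set[str]:
        out: Set[str] = set()
        for c in self.children:
            out |= c.genes()
        return out

    def to_string(self) -> str:
        parts = []
        for c in self.children:
            s = c.to_string()
            if isinstance(c, _NAry) and c.op != self.op:
                s = f"({s})"
            parts.append(s)
        return f" {self.op} ".join(parts)


class And(_NAry):
    op = "and"

    def evaluate(self, knocked_out: Set[str]) -> bool:
        return all(c.evaluate(knocked_out) for c in self.children)


class Or(_NAry):
    op = "or"

    def evaluate(self, knocked_out: Set[str]) -> bool:
        return any(c.evaluate(knocked_out) for c in self.children)


def gpr_and(existing: GPR | None, *extra: str) -> GPR | None:
    """Conjoin *extra* gene ids onto an existing rule (used for coupling)."""
    terms: list[GPR] = []
    if existing is not None:
        terms.extend(existing.children if isinstance(existing, And) else [existing])
    terms.extend(Gene(g) for g in extra)
    if not terms:
        return None
    if len(terms) == 1:
        return terms[0]
    return And(terms)


class _Parser:
    def __init__(self, tokens: list[str]):
        self.tokens = tokens
        self.pos = 0

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self) -> str:
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def parse_or(self) -> GPR:
        terms = [self.parse_and()]
        while self.peek() is not None and self.peek().lower() == "or":
            self.take()
            terms.append(self.parse_and())
        return terms[0] if len(terms) == 1 else Or(terms)

    def parse_and(self) -> GPR:
        terms = [self.parse_atom()]
        while self.peek() is not None and self.peek().lower() == "and":
            self.take()
            terms.append(self.parse_atom())
        return terms[0] if len(terms) == 1 else And(terms)

    def parse_atom(self) -> GPR:
        tok = self.peek()
        if tok is None:
            raise ValueError("unexpected end of GPR expression")
        if tok == "(":
            self.take()
            node = self.parse_or()
            if self.peek() != ")":
                raise ValueError("unbalanced parenthesis in GPR expression")
            self.take()
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise ValueError(f"unexpected token {tok!r} in GPR expression")
        return Gene(self.take())


def parse_gpr(text: str | None) -> GPR | None:
    """Parse ``"g1 and (g2 or g3)"`` style rules; empty/None gives None."""
    if text is None:
        return None
    text = text.strip()
    if not text:
        return None
    tokens = _TOKEN.findall(text)
    parser = _Parser(tokens)
    node = parser.parse_or()
    if parser.pos != len(tokens):
        raise ValueError(f"trailing tokens in GPR expression: {text!r}")
    return node
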