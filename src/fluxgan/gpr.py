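"""Gene-protein-reaction (GPR) rules.

A GPR is a boolean expression over gene identifiers in which ``and`` joins
obligate complex subunits and ``or`` joins isozymes.  For mapping expression
onto reactions the rule is evaluated numerically with AND -> min and
OR -> max of the operand expression levels; genes missing from the data are
skipped, and a rule whose genes are all missing evaluates to ``None``
(the reaction is left unmapped).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator


class GPRParseError(ValueError):
    """Malformed GPR text; carries the character offset of the problem."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at offset {offset})")
        self.offset = offset


@dataclass(frozen=True)
class GPRExpression:
    """Node of a GPR boolean tree.

    ``op`` is ``"gene"``, ``"and"`` or ``"or"``.  Leaves carry the gene id in
    ``gene``; internal nodes carry >= 2 children.
    """

    op: str
    gene: str | None = None
    children: tuple["GPRExpression", ...] = field(default=())

    def genes(self) -> set[str]:
        if self.op == "gene":
            return {self.gene}
        out: set[str] = set()
        for c in self.children:
            out |= c.genes()
        return out

    def evaluate_bool(self, active: set[str]) -> bool:
        """Boolean evaluation against a set of 'on' genes."""
        if self.op == "gene":
            return self.gene in active
        values = [c.evaluate_bool(active) for c in self.children]
        return all(values) if self.op == "and" else any(values)

    def evaluate(self, levels: dict[str, float]) -> float | None:
        """Numeric evaluation: AND = min, OR = max over *present* operands.

        Operands whose genes are entirely absent from ``levels`` are skipped;
        returns None when every gene of the rule is absent.
        """
        if self.op == "gene":
            return levels.get(self.gene)
        values = [v for v in (c.evaluate(levels) for c in self.children) if v is not None]
        if not values:
            return None
        return min(values) if self.op == "and" else max(values)

    def to_string(self) -> str:
        if self.op == "gene":
            return self.gene
        sep = f" {self.op} "
        parts = []
        for c in self.children:
            s = c.to_string()
            # parenthesize a lower-precedence OR inside an AND
            if self.op == "and" and c.op == "or":
                s = f"({s})"
            parts.append(s)
        return sep.join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


def _tokenize(text: str) -> Iterator[tuple[str, str, int]]:
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
            continue
        if ch in "()":
            yield ("paren", ch, i)
            i += 1
            continue
        j = i
        while j < n and not text[j].isspace() and text[j] not in "()":
            j += 1
        word = text[i:j]
        low = word.lower()
        if low in ("and", "or"):
            yield ("op", low, i)
        else:
            yield ("gene", word, i)
        i = j


class _Parser:
    """Recursive-descent parser; precedence parentheses > and > or."""

    def __init__(self, text: str):
        self.text = text
        self.tokens = list(_tokenize(text))
        self.pos = 0

    def peek(self) -> tuple[str, str, int] | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> tuple[str, str, int]:
        tok = self.peek()
        if tok is None:
            raise GPRParseError("unexpected end of expression", len(self.text))
        self.pos += 1
        return tok

    def parse(self) -> GPRExpression:
        expr = self.parse_or()
        tok = self.peek()
        if tok is not None:
            raise GPRParseError(f"unexpected token {tok[1]!r}", tok[2])
        return expr

    def parse_or(self) -> GPRExpression:
        terms = [self.parse_and()]
        while (tok := self.peek()) is not None and tok[:2] == ("op", "or"):
            self.next()
            terms.append(self.parse_and())
        if len(terms) == 1:
            return terms[0]
        return GPRExpression("or", children=tuple(terms))

    def parse_and(self) -> GPRExpression:
        factors = [self.parse_atom()]
        while (tok := self.peek()) is not None and tok[:2] == ("op", "and"):
            self.next()
            factors.append(self.parse_atom())
        if len(factors) == 1:
            return factors[0]
        return GPRExpression("and", children=tuple(factors))

    def parse_atom(self) -> GPRExpression:
        kind, value, offset = self.next()
        if kind == "gene":
            return GPRExpression("gene", gene=value)
        if kind == "paren" and value == "(":
            inner = self.parse_or()
            tok = self.peek()
            if tok is None or tok[:2] != ("paren", ")"):
                raise GPRParseError("unbalanced parenthesis", offset)
            self.next()
            return inner
        raise GPRParseError(f"dangling connective or stray {value!r}", offset)


def parse_gpr(text: str) -> GPRExpression | None:
    """Parse GPR text into a boolean tree; empty/blank text yields None."""
    if text is None or not text.strip():
        return None
    return _Parser(text).parse()
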