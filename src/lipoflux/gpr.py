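"""Gene-protein-reaction (GPR) boolean rules.

A GPR rule links genes to the reaction they catalyze: ``and`` denotes an
enzyme complex (every subunit required), ``or`` denotes isoenzymes (any one
suffices).  Rules are plain strings such as ``"G1 and (G2 or G3)"``; this
module parses them into an immutable tree and renders trees back to strings.

Grammar: ``and`` binds tighter than ``or``; both keywords are
case-insensitive; gene identifiers match ``[A-Za-z0-9_.:-]+``; whitespace is
insignificant.  ``parse_gpr(render_gpr(t)) == t`` for every valid tree.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = ["GPRTree", "GPRParseError", "parse_gpr", "render_gpr", "gpr_genes"]

_TOKEN_RE = re.compile(r"\s*([A-Za-z0-9_.:-]+|\(|\))")
_KEYWORDS = {"and", "or"}


class GPRParseError(ValueError):
    """Raised when a GPR rule string is malformed."""


@dataclass(frozen=True)
class GPRTree:
    """Node of a GPR boolean tree.

    ``kind`` is one of ``"gene"``, ``"and"``, ``"or"``, ``"empty"``.  Gene
    nodes carry ``gene``; and/or nodes carry at least two ``children``.
    """

    kind: str
    gene: str | None = None
    children: tuple["GPRTree", ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.kind == "gene":
            if not self.gene:
                raise ValueError("gene node requires a non-empty gene id")
        elif self.kind in ("and", "or"):
            if len(self.children) < 2:
                raise ValueError(f"{self.kind} node requires >= 2 children")
        elif self.kind != "empty":
            raise ValueError(f"unknown GPR node kind {self.kind!r}")

    @property
    def is_empty(self) -> bool:
        return self.kind == "empty"

    @staticmethod
    def empty() -> "GPRTree":
        return GPRTree("empty")

    @staticmethod
    def gene_node(gene_id: str) -> "GPRTree":
        return GPRTree("gene", gene=gene_id)

    @staticmethod
    def and_node(*children: "GPRTree") -> "GPRTree":
        return GPRTree("and", children=tuple(children))

    @staticmethod
    def or_node(*children: "GPRTree") -> "GPRTree":
        return GPRTree("or", children=tuple(children))


def _tokenize(rule: str) -> list[str]:
    tokens: list[str] = []
    pos = 0
    while pos < len(rule):
        m = _TOKEN_RE.match(rule, pos)
        if m is None:
            rest = rule[pos:].strip()
            if not rest:
                break
            raise GPRParseError(f"unexpected character at position {pos}: {rest[0]!r}")
        tokens.append(m.group(1))
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, tokens: list[str]):
        self.tokens = tokens
        self.pos = 0

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise GPRParseError("unexpected end of rule")
        self.pos += 1
        return tok

    # expr := term ('or' term)*
    def expr(self) -> GPRTree:
        terms = [self.term()]
        while (tok := self.peek()) is not None and tok.lower() == "or":
            self.next()
            terms.append(self.term())
        return terms[0] if len(terms) == 1 else GPRTree("or", children=tuple(terms))

    # term := factor ('and' factor)*
    def term(self) -> GPRTree:
        factors = [self.factor()]
        while (tok := self.peek()) is not None and tok.lower() == "and":
            self.next()
            factors.append(self.factor())
        return factors[0] if len(factors) == 1 else GPRTree("and", children=tuple(factors))

    # factor := GENE | '(' expr ')'
    def factor(self) -> GPRTree:
        tok = self.next()
        if tok == "(":
            inner = self.expr()
            closing = self.peek()
            if closing != ")":
                raise GPRParseError("unbalanced parentheses: missing ')'")
            self.next()
            return inner
        if tok == ")" or tok.lower() in _KEYWORDS:
            raise GPRParseError(f"dangling operator or misplaced token {tok!r}")
        return GPRTree("gene", gene=tok)


def parse_gpr(rule: str) -> GPRTree:
    """Parse a GPR rule string into a :class:`GPRTree`.

    Blank input yields the empty tree.  Raises :class:`GPRParseError` on
    unbalanced parentheses or dangling operators.
    """
    tokens = _tokenize(rule or "")
    if not tokens:
        return GPRTree.empty()
    parser = _Parser(tokens)
    tree = parser.expr()
    if parser.peek() is not None:
        raise GPRParseError(f"trailing tokens starting at {parser.peek()!r}")
    return tree


def render_gpr(tree: GPRTree) -> str:
    """Render a tree back to rule syntax (inverse of :func:`parse_gpr`).

    Composite children are always parenthesized so that associativity and
    precedence round-trip exactly.
    """
    if tree.kind == "empty":
        return ""
    if tree.kind == "gene":
        return tree.gene  # type: ignore[return-value]
    sep = f" {tree.kind} "
    parts = []
    for child in tree.children:
        rendered = render_gpr(child)
        parts.append(f"({rendered})" if child.kind in ("and", "or") else rendered)
    return sep.join(parts)


def gpr_genes(tree: GPRTree) -> set[str]:
    """All gene ids referenced by a GPR tree."""
    if tree.kind == "gene":
        return {tree.gene}  # type: ignore[arg-type]
    out: set[str] = set()
    for child in tree.children:
        out |= gpr_genes(child)
    return out
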