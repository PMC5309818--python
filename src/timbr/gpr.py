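"""Boolean gene–protein–reaction (GPR) rule algebra.

A GPR rule records which genes enable a reaction: ``OR`` joins redundant
isozymes (any one suffices), ``AND`` joins subunits of an enzyme complex
(all are required).  Rules are stored as canonical trees so that parsing
and serialization are mutually inverse, and so that structurally equal
rules compare equal regardless of the order they were written in.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping


class GPRParseError(ValueError):
    """Raised when a GPR string cannot be parsed."""


@dataclass(frozen=True)
class GPRRule:
    """Node of a canonical GPR tree.

    ``op`` is one of ``"gene"`` (leaf; ``gene`` holds the identifier),
    ``"and"``, ``"or"`` (``children`` holds >= 2 canonical subtrees) or
    ``"empty"`` (non-enzymatic reaction).
    """

    op: str = "empty"
    gene: str | None = None
    children: tuple["GPRRule", ...] = field(default_factory=tuple)

    # -- constructors -------------------------------------------------
    @staticmethod
    def empty() -> "GPRRule":
        return _EMPTY

    @staticmethod
    def leaf(gene_id: str) -> "GPRRule":
        if not gene_id:
            raise ValueError("gene id must be non-empty")
        return GPRRule(op="gene", gene=gene_id)

    @staticmethod
    def and_(children: Iterable["GPRRule"]) -> "GPRRule":
        return _combine("and", children)

    @staticmethod
    def or_(children: Iterable["GPRRule"]) -> "GPRRule":
        return _combine("or", children)

    # -- queries ------------------------------------------------------
    @property
    def is_empty(self) -> bool:
        return self.op == "empty"

    def genes(self) -> frozenset[str]:
        """Set of distinct gene identifiers referenced by the rule."""
        if self.op == "empty":
            return frozenset()
        if self.op == "gene":
            return frozenset({self.gene})
        out: set[str] = set()
        for child in self.children:
            out |= child.genes()
        return frozenset(out)

    def size(self) -> int:
        """Number of distinct genes (0 for the empty rule)."""
        return len(self.genes())

    def evaluate(self, present: Mapping[str, bool] | set[str] | frozenset[str]) -> bool:
        """Truth value under a gene-presence assignment.

        ``present`` is either a set of present gene ids or a mapping
        gene id -> bool.  Genes not mentioned in a mapping are absent.
        The empty rule evaluates True: a non-enzymatic reaction is never
        disabled by a gene knockout.
        """
        if self.op == "empty":
            return True
        if self.op == "gene":
            if isinstance(present, (set, frozenset)):
                return self.gene in present
            return bool(present.get(self.gene, False))
        if self.op == "and":
            return all(c.evaluate(present) for c in self.children)
        return any(c.evaluate(present) for c in self.children)

    # -- serialization ------------------------------------------------
    def to_string(self) -> str:
        """Serialize to the conventional ``and``/``or`` infix form."""
        if self.op == "empty":
            return ""
        if self.op == "gene":
            return self.gene
        if self.op == "and":
            parts = [
                f"({c.to_string()})" if c.op == "or" else c.to_string()
                for c in self.children
            ]
            return " and ".join(parts)
        parts = [c.to_string() for c in self.children]
        return " or ".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


_EMPTY = GPRRule(op="empty")


def _combine(op: str, children: Iterable[GPRRule]) -> GPRRule:
    """Canonicalize an AND/OR node: flatten same-op children, drop empties,
    deduplicate, sort deterministically, collapse singletons."""
    flat: list[GPRRule] = []
    for child in children:
        if child.is_empty:
            continue
        if child.op == op:
            flat.extend(child.children)
        else:
            flat.append(child)
    # dedupe, preserving a deterministic (sorted) order
    unique = sorted(set(flat), key=lambda r: r.to_string())
    if not unique:
        return _EMPTY
    if len(unique) == 1:
        return unique[0]
    return GPRRule(op=op, children=tuple(unique))


_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")
_GENE_RE = re.compile(r"^[A-Za-z0-9_.:\-]+$")


def _tokenize(text: str) -> list[tuple[str, int]]:
    tokens: list[tuple[str, int]] = []
    for match in _TOKEN_RE.finditer(text):
        tok = match.group(0)
        if tok not in "()":
            low = tok.lower()
            if low in ("and", "or"):
                tok = low
            elif not _GENE_RE.match(tok):
                raise GPRParseError(
                    f"invalid token {tok!r} at position {match.start()}"
                )
        tokens.append((tok, match.start()))
    return tokens


def parse_gpr(text: str) -> GPRRule:
    """Parse a GPR string into a canonical :class:`GPRRule`.

    ``and`` binds tighter than ``or`` when parentheses are absent, the
    conventional reading in constraint-based modelling.  Operators are
    case-insensitive; the empty string yields the empty rule.
    """
    tokens = _tokenize(text)
    if not tokens:
        return GPRRule.empty()
    pos = 0

    def peek() -> str | None:
        return tokens[pos][0] if pos < len(tokens) else None

    def parse_or() -> GPRRule:
        nonlocal pos
        terms = [parse_and()]
        while peek() == "or":
            pos += 1
            terms.append(parse_and())
        return GPRRule.or_(terms) if len(terms) > 1 else terms[0]

    def parse_and() -> GPRRule:
        nonlocal pos
        factors = [parse_factor()]
        while peek() == "and":
            pos += 1
            factors.append(parse_factor())
        return GPRRule.and_(factors) if len(factors) > 1 else factors[0]

    def parse_factor() -> GPRRule:
        nonlocal pos
        tok = peek()
        if tok is None:
            raise GPRParseError("unexpected end of rule")
        start = tokens[pos][1]
        if tok == "(":
            pos += 1
            inner = parse_or()
            if peek() != ")":
                raise GPRParseError(f"unbalanced parenthesis opened at position {start}")
            pos += 1
            return inner
        if tok in (")", "and", "or"):
            raise GPRParseError(f"unexpected {tok!r} at position {start}")
        pos += 1
        return GPRRule.leaf(tok)

    rule = parse_or()
    if pos != len(tokens):
        raise GPRParseError(
            f"unexpected {tokens[pos][0]!r} at position {tokens[pos][1]}"
        )
    return rule


def gpr_genes(rule: GPRRule) -> frozenset[str]:
    """Distinct gene ids referenced by ``rule``."""
    return rule.genes()


def gpr_size(rule: GPRRule) -> int:
    """Count of distinct genes in ``rule`` (0 for the empty rule)."""
    return rule.size()
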