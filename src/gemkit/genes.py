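"""Gene-protein-reaction (GPR) rules.

A GPR associates a reaction with a boolean expression over gene
identifiers: ``and`` means all subunits are required (an enzyme complex),
``or`` means alternatives exist (isozymes).  A reaction remains available
under a gene-deletion set when its expression still evaluates true with the
deleted genes set to false.

Grammar: identifiers, ``and``, ``or`` (case-insensitive), parentheses;
``and`` binds tighter than ``or``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import AbstractSet, Iterator, Union


class GeneParseError(ValueError):
    pass


@dataclass(frozen=True)
class Gene:
    name: str


@dataclass(frozen=True)
class And:
    children: tuple["GeneExpression", ...]


@dataclass(frozen=True)
class Or:
    children: tuple["GeneExpression", ...]


GeneExpression = Union[Gene, And, Or]

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def parse_genes(text: str) -> GeneExpression:
    """Parse a GPR string like ``(g1 and g2) or g3``."""
    tokens = _TOKEN_RE.findall(text)
    if not tokens:
        raise GeneParseError("empty gene expression")
    expr, pos = _parse_or(tokens, 0)
    if pos != len(tokens):
        raise GeneParseError(
            f"unexpected token {tokens[pos]!r} in gene expression {text!r}")
    return expr


def _parse_or(tokens: list[str], pos: int) -> tuple[GeneExpression, int]:
    children: list[GeneExpression] = []
    child, pos = _parse_and(tokens, pos)
    children.append(child)
    while pos < len(tokens) and tokens[pos].lower() == "or":
        child, pos = _parse_and(tokens, pos + 1)
        children.append(child)
    if len(children) == 1:
        return children[0], pos
    # Flatten associative nesting so parse(render(.)) is idempotent.
    flat: list[GeneExpression] = []
    for child in children:
        flat.extend(child.children if isinstance(child, Or) else [child])
    return Or(tuple(flat)), pos


def _parse_and(tokens: list[str], pos: int) -> tuple[GeneExpression, int]:
    children: list[GeneExpression] = []
    child, pos = _parse_atom(tokens, pos)
    children.append(child)
    while pos < len(tokens) and tokens[pos].lower() == "and":
        child, pos = _parse_atom(tokens, pos + 1)
        children.append(child)
    if len(children) == 1:
        return children[0], pos
    flat: list[GeneExpression] = []
    for child in children:
        flat.extend(child.children if isinstance(child, And) else [child])
    return And(tuple(flat)), pos


def _parse_atom(tokens: list[str], pos: int) -> tuple[GeneExpression, int]:
    if pos >= len(tokens):
        raise GeneParseError("unexpected end of gene expression")
    token = tokens[pos]
    if token == "(":
        expr, pos = _parse_or(tokens, pos + 1)
        if pos >= len(tokens) or tokens[pos] != ")":
            raise GeneParseError("unbalanced parenthesis in gene expression")
        return expr, pos + 1
    if token == ")" or token.lower() in ("and", "or"):
        raise GeneParseError(f"unexpected token {token!r} in gene expression")
    return Gene(token), pos + 1


def render_genes(expr: GeneExpression) -> str:
    """Render an expression; parsing the result reproduces the tree."""
    if isinstance(expr, Gene):
        return expr.name
    if isinstance(expr, And):
        parts = [
            f"({render_genes(c)})" if isinstance(c, Or) else render_genes(c)
            for c in expr.children
        ]
        return " and ".join(parts)
    parts = [render_genes(c) for c in expr.children]
    return " or ".join(parts)


def evaluate_genes(expr: GeneExpression, deleted: AbstractSet[str]) -> bool:
    """Evaluate with ``deleted`` genes false and every other gene true."""
    if isinstance(expr, Gene):
        return expr.name not in deleted
    if isinstance(expr, And):
        return all(evaluate_genes(c, deleted) for c in expr.children)
    return any(evaluate_genes(c, deleted) for c in expr.children)


def iter_genes(expr: GeneExpression) -> Iterator[str]:
    if isinstance(expr, Gene):
        yield expr.name
    else:
        for child in expr.children:
            yield from iter_genes(child)
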