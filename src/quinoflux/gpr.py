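"""Gene-protein-reaction (GPR) association expressions.

A GPR is a boolean expression over gene locus identifiers, e.g.
``"sdhA and sdhB"`` for an obligate complex or ``"fumC1 or fumC2"`` for
isozymes.  A reaction is available exactly when its GPR evaluates to True
with deleted genes set to False.  An empty GPR marks an orphan reaction
(no known gene), which can never be disabled by a gene deletion.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import FrozenSet, Iterable, Tuple, Union

__all__ = ["GprExpression", "GprParseError", "parse_gpr"]

# AST node: a gene id (str), or ("and"|"or", (node, node, ...))
GprNode = Union[str, Tuple[str, tuple]]

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


class GprParseError(ValueError):
    """Raised when a GPR string is not a well-formed boolean expression."""


@dataclass(frozen=True)
class GprExpression:
    """Immutable boolean tree over gene identifiers.

    ``root`` is ``None`` for the empty (orphan) expression, a gene id
    string for a single-gene association, or an ``(op, children)`` tuple.
    """

    root: GprNode | None = None

    @property
    def is_empty(self) -> bool:
        return self.root is None

    def genes(self) -> FrozenSet[str]:
        """Set of gene ids appearing as leaves."""
        out: list[str] = []

        def walk(node: GprNode) -> None:
            if isinstance(node, str):
                out.append(node)
            else:
                for child in node[1]:
                    walk(child)

        if self.root is not None:
            walk(self.root)
        return frozenset(out)

    def evaluate(self, deleted_genes: Iterable[str] = ()) -> bool:
        """Evaluate with genes in ``deleted_genes`` False, all others True.

        The empty expression evaluates True: an orphan reaction cannot be
        removed by deleting genes.
        """
        deleted = set(deleted_genes)
        if self.root is None:
            return True

        def walk(node: GprNode) -> bool:
            if isinstance(node, str):
                return node not in deleted
            op, children = node
            if op == "and":
                return all(walk(c) for c in children)
            return any(walk(c) for c in children)

        return walk(self.root)

    def to_string(self) -> str:
        """Canonical text form, parseable by :func:`parse_gpr`."""
        if self.root is None:
            return ""

        def walk(node: GprNode, parent_op: str | None) -> str:
            if isinstance(node, str):
                return node
            op, children = node
            body = f" {op} ".join(walk(c, op) for c in children)
            # parenthesise whenever nested under a different operator
            if parent_op is not None and parent_op != op:
                return f"({body})"
            return body

        return walk(self.root, None)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


def parse_gpr(text: str | None) -> GprExpression:
    """Parse a GPR string such as ``"g1 and (g2 or g3)"``.

    Grammar (standard precedence, ``and`` binds tighter than ``or``)::

        expr   := term ("or" term)*
        term   := factor ("and" factor)*
        factor := GENE | "(" expr ")"

    Empty or whitespace-only input yields the orphan expression.
    """
    if text is None or not text.strip():
        return GprExpression(None)
    tokens = _TOKEN_RE.findall(text)
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def factor() -> GprNode:
        tok = peek()
        if tok is None:
            raise GprParseError(f"unexpected end of GPR expression: {text!r}")
        if tok == "(":
            take()
            node = expr()
            if peek() != ")":
                raise GprParseError(f"unbalanced parenthesis in GPR: {text!r}")
            take()
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GprParseError(f"unexpected token {tok!r} in GPR: {text!r}")
        return take()

    def term() -> GprNode:
        nodes = [factor()]
        while peek() is not None and peek().lower() == "and":
            take()
            nodes.append(factor())
        if len(nodes) == 1:
            return nodes[0]
        return ("and", tuple(nodes))

    def expr() -> GprNode:
        nodes = [term()]
        while peek() is not None and peek().lower() == "or":
            take()
            nodes.append(term())
        if len(nodes) == 1:
            return nodes[0]
        return ("or", tuple(nodes))

    root = expr()
    if pos != len(tokens):
        raise GprParseError(f"trailing tokens in GPR: {text!r}")
    return GprExpression(root)
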