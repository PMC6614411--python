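"""Gene-protein-reaction (GPR) boolean expressions.

A GPR is a boolean tree over gene identifiers: AND nodes model enzyme
complexes (every subunit required), OR nodes model isozymes (any one
suffices).  The same tree is evaluated in two modes:

* boolean activity (``evaluate``) — is the reaction catalysable given a
  set of active genes;
* expression scoring (``score``) — map per-gene abundances onto the
  reaction with min over AND children and max over OR children, the rule
  shared by GIMME- and E-flux-style transcriptome integration.

Gene identifiers are opaque, case-sensitive strings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Optional, Union

__all__ = ["GPR", "GPRParseError", "parse_gpr"]


class GPRParseError(ValueError):
    """Raised when a GPR association string cannot be parsed."""


# A node is either a gene id (str) or ("and"|"or", [children]).
Node = Union[str, tuple]


@dataclass(frozen=True)
class GPR:
    """Immutable boolean tree over gene ids; ``root is None`` means no
    gene association (the reaction is spontaneous or non-enzymatic)."""

    root: Optional[Node] = None

    @property
    def empty(self) -> bool:
        return self.root is None

    def genes(self) -> frozenset[str]:
        """All gene ids appearing as leaves."""
        out: set[str] = set()

        def walk(node: Node) -> None:
            if isinstance(node, str):
                out.add(node)
            else:
                for child in node[1]:
                    walk(child)

        if self.root is not None:
            walk(self.root)
        return frozenset(out)

    def evaluate(self, active: Iterable[str]) -> bool:
        """Boolean activity given the set of active genes.

        An empty GPR evaluates True (no gene requirement).
        """
        if self.root is None:
            return True
        active = set(active)

        def walk(node: Node) -> bool:
            if isinstance(node, str):
                return node in active
            op, children = node
            results = (walk(c) for c in children)
            return all(results) if op == "and" else any(results)

        return walk(self.root)

    def score(self, gene_scores: Mapping[str, float]) -> Optional[float]:
        """Map per-gene abundances to a reaction-level score.

        AND -> min of measured children, OR -> max.  Unmeasured leaves are
        ignored inside an OR (an isozyme we did not measure cannot lower
        the evidence) but make an AND unscorable (a complex with an
        unmeasured subunit has unknown abundance).  Returns None when the
        whole tree is unscorable or the GPR is empty.
        """
        if self.root is None:
            return None

        def walk(node: Node) -> Optional[float]:
            if isinstance(node, str):
                return gene_scores.get(node)
            op, children = node
            vals = [walk(c) for c in children]
            if op == "and":
                if any(v is None for v in vals):
                    return None
                return min(vals)  # type: ignore[type-var]
            measured = [v for v in vals if v is not None]
            return max(measured) if measured else None

        return walk(self.root)

    def map_genes(self, fn: Callable[[str], Node]) -> "GPR":
        """Rewrite every leaf through ``fn`` (which may return a subtree)."""
        if self.root is None:
            return self

        def walk(node: Node) -> Node:
            if isinstance(node, str):
                return fn(node)
            op, children = node
            return (op, [walk(c) for c in children])

        return GPR(walk(self.root))

    def to_string(self) -> str:
        """Canonical parenthesised text form, parseable by :func:`parse_gpr`."""
        if self.root is None:
            return ""

        def walk(node: Node) -> str:
            if isinstance(node, str):
                return node
            op, children = node
            joiner = f" {op} "
            return "(" + joiner.join(walk(c) for c in children) + ")"

        return walk(self.root)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


def _tokenize(text: str) -> list[str]:
    tokens: list[str] = []
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
        elif ch in "()":
            tokens.append(ch)
            i += 1
        else:
            j = i
            while j < n and not text[j].isspace() and text[j] not in "()":
                j += 1
            tokens.append(text[i:j])
            i = j
    return tokens


def parse_gpr(text: str) -> GPR:
    """Parse a GPR association string such as ``"(g1 and g2) or g3"``.

    ``and``/``or`` are case-insensitive; ``&``/``|`` are accepted as
    aliases (both appear in legacy SBML note fields).  AND binds tighter
    than OR.  An empty or whitespace-only string yields an empty GPR.
    """
    tokens = _tokenize(text)
    if not tokens:
        return GPR(None)
    pos = 0

    def peek() -> Optional[str]:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def is_op(tok: Optional[str], name: str) -> bool:
        return tok is not None and (tok.lower() == name or tok == {"and": "&", "or": "|"}[name])

    def parse_or() -> Node:
        node = parse_and()
        children = [node]
        while is_op(peek(), "or"):
            take()
            children.append(parse_and())
        return children[0] if len(children) == 1 else ("or", children)

    def parse_and() -> Node:
        node = parse_atom()
        children = [node]
        while is_op(peek(), "and"):
            take()
            children.append(parse_atom())
        return children[0] if len(children) == 1 else ("and", children)

    def parse_atom() -> Node:
        tok = peek()
        if tok is None:
            raise GPRParseError(f"unexpected end of GPR string: {text!r}")
        if tok == "(":
            take()
            node = parse_or()
            if peek() != ")":
                raise GPRParseError(f"unbalanced parentheses in GPR: {text!r}")
            take()
            return node
        if tok == ")" or is_op(tok, "and") or is_op(tok, "or"):
            raise GPRParseError(f"unexpected token {tok!r} in GPR: {text!r}")
        return take()

    root = parse_or()
    if pos != len(tokens):
        raise GPRParseError(f"trailing tokens in GPR: {text!r}")
    return GPR(root)
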