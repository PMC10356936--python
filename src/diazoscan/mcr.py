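"""Module completion ratio (MCR) from KEGG-style module definitions.

A functional module is defined by a Boolean-algebra-like expression over KO
(KEGG Orthology) identifiers: space-separated components are all required
(AND), comma-separated alternatives inside parentheses are interchangeable
(OR), plus-joined KOs are subunits of one complex (COMPLEX), and a
minus-prefixed component is optional (OPTIONAL) and never counts against a
genome.  The completion ratio of a module for a genome's KO set is a
recursive score in [0, 100]:

    LEAF     1 if the KO is present else 0
    OR       max over alternatives
    AND      arithmetic mean over non-optional components
    COMPLEX  arithmetic mean over non-optional subunits
    OPTIONAL excluded from every denominator

The mean (rather than min) semantics gives partial credit for partially
encoded pathways, which is what "completion ratio" denotes; the exact
recursion is isolated in :func:`evaluate_mcr` so an alternative semantics
can be substituted.  Genomes are functionally classified by
complete-linkage hierarchical clustering of their MCR profiles under
Euclidean distance, after dropping modules at 0% in every genome.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

log = logging.getLogger(__name__)

MODULE_CATEGORIES = ("pathway", "complex", "functional set", "signature")

_TOKEN_RE = re.compile(r"\s+|[(),+-]|[A-Za-z0-9_.]+")
_KO_RE = re.compile(r"^[A-Za-z0-9_.]+$")


@dataclass(frozen=True)
class Node:
    """One node of a parsed module expression."""

    kind: str  # AND | OR | COMPLEX | OPTIONAL | LEAF
    children: tuple["Node", ...] = ()
    ko: str | None = None

    def leaves(self) -> set[str]:
        if self.kind == "LEAF":
            return {self.ko}
        return set().union(*(c.leaves() for c in self.children))

    def required_leaves(self) -> set[str]:
        """Leaves not under any OPTIONAL node."""
        if self.kind == "LEAF":
            return {self.ko}
        if self.kind == "OPTIONAL":
            return set()
        return set().union(*(c.required_leaves() for c in self.children))


@dataclass(frozen=True)
class ModuleDefinition:
    module_id: str
    expression: Node
    category: str = "pathway"
    definition: str = ""


class ModuleParseError(ValueError):
    def __init__(self, message: str, position: int, source: str):
        super().__init__(f"{message} at position {position} in {source!r}")
        self.position = position


class _Parser:
    """Recursive-descent parser for module definition strings.

    Grammar (loosest binding first):
        and_expr     := or_expr (WS or_expr)*
        or_expr      := complex_expr (',' complex_expr)*
        complex_expr := unary (('+' | '-') unary)*       '-' marks optional
        unary        := '-' unary | '(' and_expr ')' | KO
    """

    def __init__(self, source: str):
        self.source = source
        self.tokens: list[tuple[str, int]] = []
        pos = 0
        for m in _TOKEN_RE.finditer(source):
            if m.start() != pos:
                raise ModuleParseError(
                    f"unexpected character {source[pos]!r}", pos, source)
            tok = m.group()
            if not tok.isspace():
                self.tokens.append((tok, m.start()))
            else:
                self.tokens.append((" ", m.start()))
            pos = m.end()
        if pos != len(source):
            raise ModuleParseError(f"unexpected character {source[pos]!r}", pos, source)
        # collapse runs of whitespace, strip leading/trailing
        collapsed: list[tuple[str, int]] = []
        for tok, at in self.tokens:
            if tok == " " and (not collapsed or collapsed[-1][0] in (" ", "(", ",", "+")):
                continue
            collapsed.append((tok, at))
        while collapsed and collapsed[-1][0] == " ":
            collapsed.pop()
        self.tokens = collapsed
        self.i = 0

    def peek(self) -> str | None:
        return self.tokens[self.i][0] if self.i < len(self.tokens) else None

    def pos(self) -> int:
        return self.tokens[self.i][1] if self.i < len(self.tokens) else len(self.source)

    def take(self) -> str:
        tok = self.peek()
        self.i += 1
        return tok

    def parse(self) -> Node:
        if not self.tokens:
            raise ModuleParseError("empty definition", 0, self.source)
        node = self.and_expr()
        if self.peek() is not None:
            raise ModuleParseError(f"unexpected token {self.peek()!r}",
                                   self.pos(), self.source)
        return node

    def and_expr(self) -> Node:
        parts = [self.or_expr()]
        while self.peek() == " ":
            self.take()
            if self.peek() in (None, ")"):
                break
            parts.append(self.or_expr())
        return parts[0] if len(parts) == 1 else Node("AND", tuple(parts))

    def or_expr(self) -> Node:
        parts = [self.complex_expr()]
        while self.peek() == ",":
            self.take()
            if self.peek() in (None, ")", ","):
                raise ModuleParseError("empty alternation branch", self.pos(), self.source)
            parts.append(self.complex_expr())
        return parts[0] if len(parts) == 1 else Node("OR", tuple(parts))

    def complex_expr(self) -> Node:
        parts = [self.unary()]
        while self.peek() in ("+", "-"):
            op = self.take()
            child = self.unary()
            if op == "-":
                child = Node("OPTIONAL", (child,))
            parts.append(child)
        return parts[0] if len(parts) == 1 else Node("COMPLEX", tuple(parts))

    def unary(self) -> Node:
        tok = self.peek()
        if tok == "-":
            self.take()
            return Node("OPTIONAL", (self.unary(),))
        if tok == "(":
            at = self.pos()
            self.take()
            inner = self.and_expr()
            if self.peek() != ")":
                raise ModuleParseError("unbalanced parenthesis", at, self.source)
            self.take()
            return inner
        if tok is None or tok in (")", ",", "+"):
            raise ModuleParseError(f"expected a KO token, got {tok!r}",
                                   self.pos(), self.source)
        self.take()
        if not _KO_RE.match(tok):
            raise ModuleParseError(f"not a KO token: {tok!r}", self.pos(), self.source)
        return Node("LEAF", ko=tok)


def parse_module(definition: str, module_id: str = "",
                 category: str = "pathway") -> ModuleDefinition:
    """Parse a module definition string into an expression tree."""
    node = _Parser(definition).parse()
    return ModuleDefinition(module_id=module_id or definition, expression=node,
                            category=category, definition=definition)


def serialize(node: Node, _parent: str = "") -> str:
    """Serialize a tree back to definition syntax (round-trip equivalent)."""
    if node.kind == "LEAF":
        return node.ko
    if node.kind == "OPTIONAL":
        return "-" + serialize(node.children[0], "OPTIONAL")
    if node.kind == "AND":
        s = " ".join(serialize(c, "AND") for c in node.children)
        return f"({s})" if _parent in ("OR", "COMPLEX", "OPTIONAL") else s
    if node.kind == "OR":
        s = ",".join(serialize(c, "OR") for c in node.children)
        return f"({s})" if _parent in ("COMPLEX", "OPTIONAL", "AND") else s
    if node.kind == "COMPLEX":
        parts = []
        for i, c in enumerate(node.children):
            if c.kind == "OPTIONAL":
                parts.append("-" + serialize(c.children[0], "OPTIONAL"))
            else:
                parts.append(("+" if i else "") + serialize(c, "COMPLEX"))
        return "".join(parts)
    raise ValueError(f"unknown node kind {node.kind}")


def _score(node: Node, ko_set: set[str]) -> float:
    if node.kind == "LEAF":
        return 1.0 if node.ko in ko_set else 0.0
    if node.kind == "OR":
        return max(_score(c, ko_set) for c in node.children)
    if node.kind in ("AND", "COMPLEX"):
        required = [c for c in node.children if c.kind != "OPTIONAL"]
        if not required:
            return 0.0
        return sum(_score(c, ko_set) for c in required) / len(required)
    if node.kind == "OPTIONAL":
        return 0.0
    raise ValueError(f"unknown node kind {node.kind}")


def evaluate_mcr(module: ModuleDefinition, ko_set: set[str]) -> float:
    """Completion ratio of a module for one genome's KO set, in [0, 100]."""
    root = module.expression
    if root.kind == "OPTIONAL" or (
            root.kind in ("AND", "COMPLEX")
            and all(c.kind == "OPTIONAL" for c in root.children)):
        log.warning("module %s has no required components; scored 0", module.module_id)
        return 0.0
    return 100.0 * _score(root, ko_set)


def mcr_matrix(
    modules: dict[str, ModuleDefinition],
    ko_sets: dict[str, set[str]],
) -> pd.DataFrame:
    """Genomes x modules matrix of completion ratios (percent)."""
    genomes = sorted(ko_sets)
    module_ids = sorted(modules)
    data = [[evaluate_mcr(modules[m], ko_sets[g]) for m in module_ids]
            for g in genomes]
    return pd.DataFrame(data, index=genomes, columns=module_ids)


def cluster_profiles(profiles: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Complete-linkage Euclidean clustering of genomes by MCR profile.

    Modules at 0% in every genome are excluded first.  Genomes are ordered
    lexicographically before linkage so ties resolve deterministically.
    Returns (scipy linkage matrix, genome order).
    """
    if len(profiles) < 2:
        raise ValueError("clustering needs >=2 genomes")
    informative = profiles.loc[:, (profiles != 0).any(axis=0)]
    if informative.shape[1] == 0:
        raise ValueError("all modules are 0% in every genome; no signal to cluster")
    informative = informative.sort_index()
    Z = hierarchy.linkage(pdist(informative.to_numpy(), metric="euclidean"),
                          method="complete")
    return Z, list(informative.index)


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage matrix as a newick tree with branch lengths."""
    tree = hierarchy.to_tree(Z)

    def build(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = build(node.left, node.dist)
        right = build(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return build(tree, tree.dist) + ";"
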