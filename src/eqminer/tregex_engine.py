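"""A small tree-query language over semantically typed phrase-structure trees.

The dialect covers exactly what the nine built-in extraction patterns need:

* node tests: a bare identifier matches a node label by exact string
  equality; ``/regex/`` matches by unanchored regex search (so ``/PATO/``
  hits a SEM leaf labelled ``PATO:0000574;SNOMEDCT:...``);
* ``A < B`` — B matches an immediate child of A;
* ``A ++ B`` — B matches a sister of A strictly to its right (any distance);
* ``A + CC B`` — coordination: B matches a sister strictly to the right of A
  with a CC-labelled sister strictly between them.

Relations chain on the head of a group: ``JJ < X ++ Y`` constrains the same
JJ node.  Parentheses group sub-patterns.

:func:`match` is the production matcher; :func:`brute_force_match`
re-derives the same result set by exhaustive enumeration of label-compatible
assignments and serves as the verification oracle.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Iterator, Sequence

from .corpus_model import ParseTree

__all__ = [
    "Relation",
    "NodeTest",
    "Pattern",
    "MatchResult",
    "PatternSyntaxError",
    "parse_pattern",
    "serialize_pattern",
    "load_pattern_file",
    "builtin_patterns",
    "match",
    "brute_force_match",
]


class Relation(Enum):
    CHILD = "<"
    RIGHT_SISTER = "++"
    COORD_SISTER = "+CC"


@dataclass(frozen=True)
class NodeTest:
    """A label test: exact identifier or unanchored ``/regex/``."""

    source: str
    is_regex: bool

    def matches(self, label: str) -> bool:
        if self.is_regex:
            return re.search(self.source, label) is not None
        return label == self.source

    def __str__(self) -> str:
        return f"/{self.source}/" if self.is_regex else self.source


@dataclass
class Pattern:
    """A pattern node: a label test plus ordered relation clauses."""

    test: NodeTest
    relations: list[tuple[Relation, "Pattern"]] = field(default_factory=list)

    def nodes(self) -> list["Pattern"]:
        """All pattern nodes in preorder (self first)."""
        out = [self]
        for _, operand in self.relations:
            out.extend(operand.nodes())
        return out

    def __str__(self) -> str:
        return serialize_pattern(self)


@dataclass
class MatchResult:
    """One way of binding the pattern nodes to tree nodes."""

    root_node: ParseTree
    bindings: dict[int, ParseTree]  # pattern-node preorder index -> tree node

    def binding_key(self, positions: dict[int, int]) -> tuple[int, ...]:
        return tuple(positions[id(self.bindings[i])] for i in sorted(self.bindings))


class PatternSyntaxError(ValueError):
    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


# ---------------------------------------------------------------------------
# Pattern parsing

_TOKEN_RE = re.compile(r"\s*(?:(?P<lparen>\()|(?P<rparen>\))|(?P<sis>\+\+)"
                       r"|(?P<plus>\+)|(?P<child><)|(?P<regex>/(?:[^/\\]|\\.)*/)"
                       r"|(?P<ident>[^\s()<+/]+))")


def _tokenize_pattern(text: str) -> list[tuple[str, str, int]]:
    tokens: list[tuple[str, str, int]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if not m:
            stripped = text[pos:].lstrip()
            if not stripped:
                break
            raise PatternSyntaxError(
                f"unexpected character {stripped[0]!r}", len(text) - len(stripped)
            )
        pos = m.end()
        for kind in ("lparen", "rparen", "sis", "plus", "child", "regex", "ident"):
            value = m.group(kind)
            if value is not None:
                tokens.append((kind, value, m.start(kind)))
                break
    return tokens


def parse_pattern(text: str) -> Pattern:
    """Parse a pattern expression into its AST."""
    tokens = _tokenize_pattern(text)
    if not tokens:
        raise PatternSyntaxError("empty pattern", 0)
    pos = 0

    def peek() -> tuple[str, str, int] | None:
        return tokens[pos] if pos < len(tokens) else None

    def parse_group() -> Pattern:
        """pattern := primary (relation primary)* — relations chain on the head."""
        nonlocal pos
        head = parse_primary()
        while True:
            tok = peek()
            if tok is None or tok[0] == "rparen":
                break
            relation = parse_relation()
            operand = parse_primary()
            head.relations.append((relation, operand))
        return head

    def parse_relation() -> Relation:
        nonlocal pos
        kind, value, offset = tokens[pos]
        if kind == "child":
            pos += 1
            return Relation.CHILD
        if kind == "sis":
            pos += 1
            return Relation.RIGHT_SISTER
        if kind == "plus":
            pos += 1
            tok = peek()
            if tok is None or tok[0] != "ident" or tok[1] != "CC":
                raise PatternSyntaxError("'+' must be followed by CC", offset)
            pos += 1
            return Relation.COORD_SISTER
        raise PatternSyntaxError(f"expected relation operator, got {value!r}", offset)

    def parse_primary() -> Pattern:
        nonlocal pos
        tok = peek()
        if tok is None:
            raise PatternSyntaxError("unexpected end of pattern", len(text))
        kind, value, offset = tok
        if kind == "lparen":
            pos += 1
            inner = parse_group()
            tok = peek()
            if tok is None or tok[0] != "rparen":
                raise PatternSyntaxError("unbalanced parentheses: missing ')'", offset)
            pos += 1
            return inner
        if kind == "regex":
            pos += 1
            return Pattern(NodeTest(value[1:-1], is_regex=True))
        if kind == "ident":
            pos += 1
            return Pattern(NodeTest(value, is_regex=False))
        raise PatternSyntaxError(f"unexpected token {value!r}", offset)

    result = parse_group()
    tok = peek()
    if tok is not None:
        raise PatternSyntaxError(f"trailing content {tok[1]!r}", tok[2])
    return result


def serialize_pattern(pattern: Pattern) -> str:
    """Render a pattern back to source form (parses to an equivalent AST)."""

    def render(p: Pattern, top: bool) -> str:
        head = str(p.test)
        if not p.relations:
            return head
        parts = [head]
        for relation, operand in p.relations:
            op = "< " if relation is Relation.CHILD else (
                "++ " if relation is Relation.RIGHT_SISTER else "+ CC "
            )
            parts.append(op + render(operand, top=False))
        body = " ".join(parts)
        return body if top else f"({body})"

    return render(pattern, top=True)


def load_pattern_file(path: str) -> list[tuple[str, Pattern]]:
    """Load one pattern per line; '#' starts a comment. Returns (id, Pattern) pairs."""
    patterns: list[tuple[str, Pattern]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            patterns.append((f"p{len(patterns) + 1}", parse_pattern(line)))
    return patterns


def builtin_patterns() -> list[tuple[str, Pattern]]:
    """The nine built-in phenotype extraction patterns."""
    text = resources.files("eqminer").joinpath("patterns/builtin9.tgx").read_text()
    patterns: list[tuple[str, Pattern]] = []
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            patterns.append((f"p{len(patterns) + 1}", parse_pattern(line)))
    return patterns


# ---------------------------------------------------------------------------
# Matching

def _tree_index(tree: ParseTree):
    """Preorder positions, parent links and child ranks for every node."""
    positions: dict[int, int] = {}
    parents: dict[int, ParseTree | None] = {id(tree): None}
    ranks: dict[int, int] = {}
    order: list[ParseTree] = []
    for node in tree.preorder():
        positions[id(node)] = len(order)
        order.append(node)
        for rank, child in enumerate(node.children):
            parents[id(child)] = node
            ranks[id(child)] = rank
    return positions, parents, ranks, order


def _relation_holds(
    relation: Relation,
    a: ParseTree,
    b: ParseTree,
    parents: dict[int, ParseTree | None],
    ranks: dict[int, int],
) -> bool:
    if relation is Relation.CHILD:
        return any(c is b for c in a.children)
    parent = parents.get(id(a))
    if parent is None or parents.get(id(b)) is not parent:
        return False
    ra, rb = ranks[id(a)], ranks[id(b)]
    if rb <= ra:
        return False
    if relation is Relation.RIGHT_SISTER:
        return True
    # COORD_SISTER: a CC-labelled sister strictly between a and b
    return any(
        c.label == "CC" for c in parent.children[ra + 1 : rb]
    )


def match(pattern: Pattern, tree: ParseTree) -> list[MatchResult]:
    """All distinct bindings of the pattern into the tree.

    Results are ordered by preorder position of the matched root, then by
    the preorder positions of the remaining bound nodes.
    """
    positions, parents, ranks, order = _tree_index(tree)
    pattern_nodes = pattern.nodes()
    node_index = {id(p): i for i, p in enumerate(pattern_nodes)}
    results: list[MatchResult] = []
    seen: set[tuple[int, ...]] = set()

    def extend(p: Pattern, node: ParseTree, bindings: dict[int, ParseTree]) -> Iterator[dict[int, ParseTree]]:
        """Bind pattern node p to tree node, then satisfy its relations."""
        if not p.test.matches(node.label):
            return
        bindings = dict(bindings)
        bindings[node_index[id(p)]] = node

        def satisfy(rel_idx: int, bnd: dict[int, ParseTree]) -> Iterator[dict[int, ParseTree]]:
            if rel_idx == len(p.relations):
                yield bnd
                return
            relation, operand = p.relations[rel_idx]
            if relation is Relation.CHILD:
                candidates: Sequence[ParseTree] = node.children
            else:
                parent = parents.get(id(node))
                if parent is None:
                    return
                rank = ranks[id(node)]
                if relation is Relation.RIGHT_SISTER:
                    candidates = parent.children[rank + 1 :]
                else:
                    sisters = parent.children
                    candidates = [
                        s
                        for j, s in enumerate(sisters)
                        if j > rank
                        and any(c.label == "CC" for c in sisters[rank + 1 : j])
                    ]
            for cand in candidates:
                for sub in extend(operand, cand, bnd):
                    yield from satisfy(rel_idx + 1, sub)

        yield from satisfy(0, bindings)

    for node in order:
        for bindings in extend(pattern, node, {}):
            key = tuple(positions[id(bindings[i])] for i in range(len(pattern_nodes)))
            if key not in seen:
                seen.add(key)
                results.append(MatchResult(root_node=bindings[0], bindings=bindings))

    results.sort(
        key=lambda r: tuple(positions[id(r.bindings[i])] for i in range(len(pattern_nodes)))
    )
    return results


_BRUTE_FORCE_NODE_LIMIT = 40
_BRUTE_FORCE_ASSIGNMENT_LIMIT = 20_000_000


def brute_force_match(pattern: Pattern, tree: ParseTree) -> list[MatchResult]:
    """Oracle matcher: enumerate every label-compatible assignment and filter.

    Definitionally equivalent to :func:`match`; refuses trees over 40 nodes.
    """
    positions, parents, ranks, order = _tree_index(tree)
    if len(order) > _BRUTE_FORCE_NODE_LIMIT:
        raise ValueError(
            f"brute_force_match limited to {_BRUTE_FORCE_NODE_LIMIT} nodes, got {len(order)}"
        )
    pattern_nodes = pattern.nodes()
    node_index = {id(p): i for i, p in enumerate(pattern_nodes)}

    # constraint list: (parent pattern idx, relation, child pattern idx)
    constraints: list[tuple[int, Relation, int]] = []

    def collect(p: Pattern) -> None:
        for relation, operand in p.relations:
            constraints.append((node_index[id(p)], relation, node_index[id(operand)]))
            collect(operand)

    collect(pattern)

    candidate_lists = [
        [n for n in order if p.test.matches(n.label)] for p in pattern_nodes
    ]
    total = 1
    for lst in candidate_lists:
        total *= len(lst)
        if total > _BRUTE_FORCE_ASSIGNMENT_LIMIT:
            raise ValueError("assignment space too large for brute force")
    if total == 0:
        return []

    import itertools

    results: list[MatchResult] = []
    seen: set[tuple[int, ...]] = set()
    for assignment in itertools.product(*candidate_lists):
        if all(
            _relation_holds(rel, assignment[i], assignment[j], parents, ranks)
            for i, rel, j in constraints
        ):
            key = tuple(positions[id(n)] for n in assignment)
            if key not in seen:
                seen.add(key)
                results.append(
                    MatchResult(
                        root_node=assignment[0],
                        bindings={i: n for i, n in enumerate(assignment)},
                    )
                )
    results.sort(
        key=lambda r: tuple(positions[id(r.bindings[i])] for i in range(len(pattern_nodes)))
    )
    return results
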