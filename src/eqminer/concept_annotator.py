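"""Lexicon-driven concept recognition and assembly of semantically typed trees.

A :class:`Lexicon` maps lowercased surface terms (possibly multi-token) to
ontology concept IDs under a single namespace (PATO, FMA, HP, ...).  The
annotator performs greedy leftmost-longest dictionary matching per namespace;
matches are then projected onto the parse tree as ``SEM`` children of the
preterminals covering each matched token.

The SEM leaf label is the ``;``-joined sorted list of ``NAMESPACE:ID``
entries for that token, so downstream tree patterns can test concept
membership with an unanchored regex such as ``/PATO/``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .corpus_model import ParseTree

__all__ = [
    "Lexicon",
    "ConceptAnnotation",
    "SEM_LABEL",
    "load_lexicon",
    "load_lexicon_tsv",
    "load_lexicon_obo",
    "annotate",
    "assemble_semantic_tree",
    "strip_sem",
    "sem_concepts",
]

SEM_LABEL = "SEM"

_NAMESPACE_RE = re.compile(r"^[A-Z][A-Z0-9_]*$")


@dataclass
class Lexicon:
    """Surface-term to concept-ID dictionary for one ontology namespace."""

    namespace: str
    entries: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not _NAMESPACE_RE.match(self.namespace):
            raise ValueError(
                f"namespace must be uppercase without '/' or '|': {self.namespace!r}"
            )
        for term in self.entries:
            if not term or term != term.lower():
                raise ValueError(f"lexicon terms must be non-empty lowercase: {term!r}")

    def add(self, term: str, concept_id: str) -> None:
        term = " ".join(term.lower().split())
        if not term:
            raise ValueError("empty lexicon term")
        ids = self.entries.setdefault(term, [])
        if concept_id not in ids:
            ids.append(concept_id)

    @property
    def max_term_tokens(self) -> int:
        if not self.entries:
            return 0
        return max(len(t.split()) for t in self.entries)


@dataclass(frozen=True)
class ConceptAnnotation:
    """A concept hit over a half-open token span [token_start, token_end)."""

    token_start: int
    token_end: int
    namespace: str
    concept_id: str

    def __post_init__(self) -> None:
        if self.token_start < 0 or self.token_start >= self.token_end:
            raise ValueError("annotation span must satisfy 0 <= start < end")


def load_lexicon(path: str, format: str = "tsv", namespace: str | None = None) -> Lexicon:
    """Load a lexicon from a TSV or OBO file.

    TSV columns are ``term``, ``concept_id``, ``namespace`` (header optional).
    For OBO input the namespace is taken from ``namespace=`` or must be given.
    """
    if format == "tsv":
        return load_lexicon_tsv(path)
    if format == "obo":
        return load_lexicon_obo(path, namespace=namespace)
    raise ValueError(f"unknown lexicon format: {format!r}")


def load_lexicon_tsv(path: str) -> Lexicon:
    lexicon: Lexicon | None = None
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and [p.strip().lower() for p in parts[:3]] == [
                "term",
                "concept_id",
                "namespace",
            ]:
                continue
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields")
            term, concept_id, ns = (p.strip() for p in parts[:3])
            if not term or not concept_id or not ns:
                raise ValueError(f"{path}:{lineno}: empty field")
            if lexicon is None:
                lexicon = Lexicon(ns)
            elif ns != lexicon.namespace:
                raise ValueError(
                    f"{path}:{lineno}: mixed namespaces {lexicon.namespace!r} and {ns!r}"
                )
            lexicon.add(term, concept_id)
    if lexicon is None:
        raise ValueError(f"{path}: no lexicon entries")
    return lexicon


_OBO_SYNONYM_RE = re.compile(r'^synonym:\s*"(?P<text>(?:[^"\\]|\\.)*)"\s*(?P<scope>\w+)?')


def load_lexicon_obo(path: str, namespace: str | None = None) -> Lexicon:
    """Load term names and EXACT synonyms from an OBO 1.2 flat file."""
    ns = namespace
    terms: list[tuple[str, str]] = []  # (surface, concept_id)
    cur_id: str | None = None
    in_term = False
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line == "[Term]":
                in_term = True
                cur_id = None
                continue
            if line.startswith("["):
                in_term = False
                continue
            if ns is None and line.startswith("default-namespace:"):
                ns = line.split(":", 1)[1].strip().upper()
            if not in_term:
                continue
            if line.startswith("id:"):
                cur_id = line.split(":", 1)[1].strip()
            elif line.startswith("name:") and cur_id:
                terms.append((line.split(":", 1)[1].strip(), cur_id))
            elif line.startswith("synonym:") and cur_id:
                m = _OBO_SYNONYM_RE.match(line)
                if m and (m.group("scope") or "").upper() == "EXACT":
                    terms.append((m.group("text").replace('\\"', '"'), cur_id))
    if ns is None:
        # fall back to the prefix of the first term id (e.g. PATO:0000574 -> PATO)
        for _, cid in terms:
            if ":" in cid:
                ns = cid.split(":", 1)[0].upper()
                break
    if ns is None:
        raise ValueError(f"{path}: cannot determine OBO namespace")
    lexicon = Lexicon(ns)
    for surface, cid in terms:
        lexicon.add(surface, cid)
    return lexicon


def annotate(
    tokens: Sequence[str], lexicons: Iterable[Lexicon]
) -> list[ConceptAnnotation]:
    """Greedy leftmost-longest dictionary matching, per namespace independently.

    Within one namespace a token belongs to at most one match; hits from
    different namespaces may overlap freely.  Matching is case-insensitive.
    """
    if not tokens:
        raise ValueError("tokens must be non-empty")
    lowered = [t.lower() for t in tokens]
    out: list[ConceptAnnotation] = []
    for lexicon in lexicons:
        max_len = lexicon.max_term_tokens
        i = 0
        while i < len(lowered):
            matched = 0
            for span in range(min(max_len, len(lowered) - i), 0, -1):
                term = " ".join(lowered[i : i + span])
                ids = lexicon.entries.get(term)
                if ids:
                    for cid in ids:
                        out.append(
                            ConceptAnnotation(i, i + span, lexicon.namespace, cid)
                        )
                    matched = span
                    break
            i += matched if matched else 1
    out.sort(key=lambda a: (a.token_start, a.token_end, a.namespace, a.concept_id))
    return out


def assemble_semantic_tree(
    tree: ParseTree, annotations: Sequence[ConceptAnnotation]
) -> ParseTree:
    """Attach SEM children to preterminals covering annotated tokens.

    Multi-token annotations project onto every covered token's preterminal.
    The input tree is not modified; stripping all SEM nodes from the result
    recovers it exactly.
    """
    result = tree.copy()
    leaves = result.leaves()
    n = len(leaves)
    # preterminal lookup by leaf identity
    parent_of: dict[int, ParseTree] = {}
    for node in result.preorder():
        for child in node.children:
            if child.is_leaf:
                parent_of[id(child)] = node
    concepts_by_token: dict[int, set[str]] = {}
    for ann in annotations:
        if ann.token_end > n:
            raise IndexError(
                f"annotation span ({ann.token_start}, {ann.token_end}) beyond yield of length {n}"
            )
        prefix = f"{ann.namespace}:"
        entry = (
            ann.concept_id
            if ann.concept_id.startswith(prefix)
            else prefix + ann.concept_id
        )
        for idx in range(ann.token_start, ann.token_end):
            concepts_by_token.setdefault(idx, set()).add(entry)
    for idx, concepts in sorted(concepts_by_token.items()):
        preterminal = parent_of[id(leaves[idx])]
        sem_leaf = ParseTree(";".join(sorted(concepts)))
        preterminal.children.append(ParseTree(SEM_LABEL, [sem_leaf]))
    return result


def strip_sem(tree: ParseTree) -> ParseTree:
    """Remove all SEM nodes, recovering the plain parse tree."""
    children = [strip_sem(c) for c in tree.children if c.label != SEM_LABEL]
    return ParseTree(tree.label, children)


def sem_concepts(tree: ParseTree) -> list[str]:
    """All NAMESPACE:ID entries carried by SEM nodes in a subtree (deduplicated, sorted)."""
    out: set[str] = set()
    for node in tree.preorder():
        if node.label == SEM_LABEL and node.children:
            out.update(node.children[0].label.split(";"))
    return sorted(c for c in out if c)
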