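"""Core sentence/tree data types, bracketed-tree I/O and trigger-based sentence selection.

Parse trees are plain Penn-Treebank style bracketed structures.  Sentences
enter the pipeline as TSV records carrying a PMID, a sentence index, the raw
text and (optionally) a bracketed tree produced by an external parser.
"""

from __future__ import annotations

import csv
import re
import sys
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

__all__ = [
    "ParseTree",
    "SentenceRecord",
    "TriggerSet",
    "DEFAULT_TRIGGER_STEMS",
    "PTBParseError",
    "read_ptb",
    "write_ptb",
    "tokenize",
    "select_trigger_sentences",
    "read_sentences_tsv",
    "write_sentences_tsv",
]

#: The eleven built-in prefix stems used to select candidate sentences.
DEFAULT_TRIGGER_STEMS = frozenset(
    {
        "abnormal",
        "characteristic",
        "aberra",
        "defect",
        "atypical",
        "unusual",
        "irregular",
        "anomal",
        "unhealthy",
        "inactiv",
        "inadeq",
    }
)


@dataclass
class ParseTree:
    """A node of a phrase-structure tree.

    ``label`` holds the phrase category at internal nodes, the
    part-of-speech at preterminals and the word itself at leaves.  A node is
    a leaf iff ``children`` is empty.
    """

    label: str
    children: list["ParseTree"] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("ParseTree label must be non-empty")

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def is_preterminal(self) -> bool:
        return len(self.children) >= 1 and all(c.is_leaf for c in self.children)

    def leaves(self) -> list["ParseTree"]:
        """Left-to-right leaf nodes."""
        if self.is_leaf:
            return [self]
        out: list[ParseTree] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def yield_tokens(self) -> list[str]:
        """The token sequence spelled by the leaves."""
        return [leaf.label for leaf in self.leaves()]

    def preorder(self) -> Iterator["ParseTree"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def copy(self) -> "ParseTree":
        return ParseTree(self.label, [c.copy() for c in self.children])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ParseTree):
            return NotImplemented
        return self.label == other.label and self.children == other.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"ParseTree({write_ptb(self)!r})"


@dataclass
class SentenceRecord:
    """One sentence of the corpus, keyed by document (PMID) and position."""

    doc_id: str
    sent_index: int
    text: str
    tokens: Optional[list[str]] = None
    tree: Optional[ParseTree] = None

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValueError("doc_id must be non-empty")
        if self.sent_index < 0:
            raise ValueError("sent_index must be non-negative")
        if self.tree is not None and self.tokens is not None:
            if self.tree.yield_tokens() != self.tokens:
                raise ValueError(
                    f"tree yield does not equal tokens for {self.doc_id}:{self.sent_index}"
                )

    def effective_tokens(self) -> list[str]:
        """Tokens if supplied, else the tree yield, else a whitespace/punct split of text."""
        if self.tokens is not None:
            return self.tokens
        if self.tree is not None:
            return self.tree.yield_tokens()
        return tokenize(self.text)


@dataclass(frozen=True)
class TriggerSet:
    """A set of lowercase prefix stems that select sentences for parsing."""

    stems: frozenset[str] = DEFAULT_TRIGGER_STEMS

    def __post_init__(self) -> None:
        for stem in self.stems:
            if not stem or any(ch.isspace() for ch in stem):
                raise ValueError(f"invalid trigger stem: {stem!r}")
            if stem != stem.lower():
                raise ValueError(f"trigger stem must be lowercase: {stem!r}")

    def matches_token(self, token: str) -> bool:
        stripped = token.strip("".join(_PUNCT)).lower()
        return any(stripped.startswith(stem) for stem in self.stems)

    def matches(self, tokens: Iterable[str]) -> bool:
        return any(self.matches_token(t) for t in tokens)


_PUNCT = ".,;:!?\"'()[]{}<>/\\|`~"

_TOKEN_RE = re.compile(r"\w+|[^\w\s]")


def tokenize(text: str) -> list[str]:
    """Whitespace + punctuation tokenization (fallback when no tokens given)."""
    return _TOKEN_RE.findall(text)


class PTBParseError(ValueError):
    """Raised on malformed bracketed-tree input; carries the character offset."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at offset {offset})")
        self.offset = offset


_PTB_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def read_ptb(text: str) -> ParseTree:
    """Parse a single bracketed tree.

    Accepts standard PTB notation ``(LABEL child child ...)`` where each
    child is either a nested tree or a bare word leaf.  A bare token on its
    own is a single leaf node.
    """
    if not text or not text.strip():
        raise PTBParseError("empty input", 0)

    tokens: list[tuple[str, int]] = [
        (m.group(0), m.start()) for m in _PTB_TOKEN_RE.finditer(text)
    ]
    pos = 0

    def parse_node() -> ParseTree:
        nonlocal pos
        tok, off = tokens[pos]
        if tok == ")":
            raise PTBParseError("unexpected ')'", off)
        if tok != "(":
            pos += 1
            return ParseTree(tok)
        # '(' LABEL children ')'
        pos += 1
        if pos >= len(tokens):
            raise PTBParseError("unexpected end of input after '('", len(text))
        label_tok, label_off = tokens[pos]
        if label_tok in "()":
            raise PTBParseError("expected node label", label_off)
        pos += 1
        children: list[ParseTree] = []
        while True:
            if pos >= len(tokens):
                raise PTBParseError("unbalanced brackets: missing ')'", len(text))
            tok, off = tokens[pos]
            if tok == ")":
                pos += 1
                break
            children.append(parse_node())
        return ParseTree(label_tok, children)

    tree = parse_node()
    if pos != len(tokens):
        raise PTBParseError("trailing content after tree", tokens[pos][1])
    return tree


def write_ptb(tree: ParseTree) -> str:
    """Serialize a tree to single-line bracket notation (inverse of :func:`read_ptb`)."""
    if tree.is_leaf:
        return tree.label
    inner = " ".join(write_ptb(c) for c in tree.children)
    return f"({tree.label} {inner})"


def select_trigger_sentences(
    sentences: Sequence[SentenceRecord],
    triggers: TriggerSet | None = None,
) -> list[SentenceRecord]:
    """Keep exactly the sentences containing at least one trigger-stem token.

    Matching is case-insensitive, prefix-based, after stripping surrounding
    punctuation from each token.  Input order is preserved.
    """
    triggers = triggers or TriggerSet()
    return [s for s in sentences if triggers.matches(s.effective_tokens())]


# ---------------------------------------------------------------------------
# TSV I/O

_TSV_COLUMNS = ["pmid", "sent_index", "text", "ptb_tree"]


def read_sentences_tsv(path: str) -> list[SentenceRecord]:
    """Read sentence records from a TSV with columns pmid, sent_index, text, ptb_tree."""
    records: list[SentenceRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(_TSV_COLUMNS[:3]) - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"sentence TSV missing columns: {sorted(missing)}")
        for row in reader:
            tree_str = (row.get("ptb_tree") or "").strip()
            tree = read_ptb(tree_str) if tree_str else None
            records.append(
                SentenceRecord(
                    doc_id=row["pmid"],
                    sent_index=int(row["sent_index"]),
                    text=row["text"],
                    tokens=tree.yield_tokens() if tree is not None else None,
                    tree=tree,
                )
            )
    return records


def write_sentences_tsv(records: Sequence[SentenceRecord], path: str) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(_TSV_COLUMNS)
        for rec in records:
            writer.writerow(
                [
                    rec.doc_id,
                    rec.sent_index,
                    rec.text,
                    write_ptb(rec.tree) if rec.tree is not None else "",
                ]
            )
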