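"""Phenotype candidate extraction, normalization, df filtering and record export.

Pattern matches are turned into :class:`PhenotypeCandidate` records carrying
the decomposed quality/entity concept links, deduplicated corpus-wide on the
normalized surface form.  Candidates are filtered against a local
:class:`DocumentIndex` (term -> PMID list) by document frequency, then
exported as XML (schema shipped in ``schema/records.xsd``) or JSON lines.
"""

from __future__ import annotations

import datetime as _dt
import json
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .concept_annotator import SEM_LABEL
from .corpus_model import ParseTree, SentenceRecord
from .tregex_engine import Pattern, match

__all__ = [
    "QUALITY_NAMESPACES",
    "ENTITY_NAMESPACES",
    "PhenotypeCandidate",
    "DocumentIndex",
    "extract_candidates",
    "normalize_term",
    "filter_by_df",
    "stratify_df",
    "DfStrata",
    "export_records",
    "import_records",
]

#: Namespaces counted as qualities vs. entities when decomposing a match.
QUALITY_NAMESPACES = frozenset({"PATO"})
ENTITY_NAMESPACES = frozenset(
    {"FMA", "RXNORM", "CHEBI", "MA", "MP", "HP", "DOID", "ORDO", "OMIM"}
)

_DETERMINERS = {"a", "an", "the"}


@dataclass
class PhenotypeCandidate:
    """An extracted phenotype with EQ concept links and provenance."""

    pm_id: str
    surface: str
    normalized: str
    quality_concepts: list[str]
    entity_concepts: list[str]
    source: list[tuple[str, int, str]]  # (PMID, sent_index, pattern_id)
    df: int = 0
    df_pmids: list[str] = field(default_factory=list)

    def validate(self) -> None:
        if not self.quality_concepts:
            raise ValueError(f"{self.pm_id}: no quality concepts")
        if not self.entity_concepts:
            raise ValueError(f"{self.pm_id}: no entity concepts")
        if self.df_pmids and self.df != len(set(self.df_pmids)):
            raise ValueError(f"{self.pm_id}: df does not match df_pmids")


@dataclass
class DocumentIndex:
    """Local stand-in for a literature search: normalized term -> PMID list."""

    terms: dict[str, list[str]] = field(default_factory=dict)
    cap: int = 10_000

    def __post_init__(self) -> None:
        for term, pmids in self.terms.items():
            deduped = list(dict.fromkeys(pmids))[: self.cap]
            self.terms[term] = deduped

    def lookup(self, term: str) -> list[str]:
        return self.terms.get(term, [])

    @classmethod
    def read_tsv(cls, path: str, cap: int = 10_000) -> "DocumentIndex":
        terms: dict[str, list[str]] = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                term, _, pmid_field = line.partition("\t")
                pmids = [p for p in pmid_field.split(",") if p]
                terms[term] = pmids
        return cls(terms, cap=cap)

    def write_tsv(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for term in sorted(self.terms):
                fh.write(f"{term}\t{','.join(self.terms[term])}\n")


def normalize_term(surface: str) -> str:
    """Lowercase, strip leading determiners, collapse internal whitespace."""
    if not surface:
        raise ValueError("empty surface form")
    words = surface.lower().split()
    while words and words[0] in _DETERMINERS:
        words = words[1:]
    return " ".join(words)


def _word_yield(tree: ParseTree) -> list[str]:
    """Leaf words of a subtree, skipping SEM annotation nodes."""
    if tree.label == SEM_LABEL:
        return []
    if tree.is_leaf:
        return [tree.label]
    out: list[str] = []
    for c in tree.children:
        out.extend(_word_yield(c))
    return out


def _subtree_concepts(tree: ParseTree) -> tuple[list[str], list[str]]:
    qualities: set[str] = set()
    entities: set[str] = set()
    for node in tree.preorder():
        if node.label == SEM_LABEL and node.children:
            for entry in node.children[0].label.split(";"):
                ns = entry.split(":", 1)[0]
                if ns in QUALITY_NAMESPACES:
                    qualities.add(entry)
                elif ns in ENTITY_NAMESPACES:
                    entities.add(entry)
    return sorted(qualities), sorted(entities)


def extract_candidates(
    trees: Sequence[tuple[SentenceRecord, ParseTree]],
    patterns: Sequence[tuple[str, Pattern]],
) -> list[PhenotypeCandidate]:
    """Run every pattern over every annotated tree and merge matches.

    The surface form of a match is the word yield of the matched subtree
    root (SEM leaves excluded).  Matches sharing a root within one sentence
    collapse to a single occurrence; candidates are deduplicated corpus-wide
    on the normalized form, merging provenance and concept links.  Accession
    numbers PM1, PM2, ... follow first occurrence order.
    """
    by_norm: dict[str, PhenotypeCandidate] = {}
    order: list[str] = []
    for record, tree in trees:
        for pattern_id, pattern in patterns:
            seen_roots: set[int] = set()
            for result in match(pattern, tree):
                root = result.root_node
                if id(root) in seen_roots:
                    continue
                seen_roots.add(id(root))
                surface = " ".join(_word_yield(root))
                normalized = normalize_term(surface)
                qualities, entities = _subtree_concepts(root)
                source_entry = (record.doc_id, record.sent_index, pattern_id)
                cand = by_norm.get(normalized)
                if cand is None:
                    cand = PhenotypeCandidate(
                        pm_id="",  # assigned below
                        surface=surface,
                        normalized=normalized,
                        quality_concepts=qualities,
                        entity_concepts=entities,
                        source=[source_entry],
                    )
                    by_norm[normalized] = cand
                    order.append(normalized)
                else:
                    if source_entry not in cand.source:
                        cand.source.append(source_entry)
                    cand.quality_concepts = sorted(
                        set(cand.quality_concepts) | set(qualities)
                    )
                    cand.entity_concepts = sorted(
                        set(cand.entity_concepts) | set(entities)
                    )
    candidates = [by_norm[n] for n in order]
    for i, cand in enumerate(candidates, start=1):
        cand.pm_id = f"PM{i}"
        cand.validate()
    return candidates


def filter_by_df(
    candidates: Sequence[PhenotypeCandidate],
    index: DocumentIndex,
    min_df: int = 10,
) -> list[PhenotypeCandidate]:
    """Populate df from the index and keep candidates with df >= min_df."""
    kept: list[PhenotypeCandidate] = []
    for cand in candidates:
        pmids = index.lookup(cand.normalized)
        cand.df_pmids = list(dict.fromkeys(pmids))
        cand.df = len(cand.df_pmids)
        if cand.df >= min_df:
            kept.append(cand)
    return kept


@dataclass
class DfStrata:
    """Document-frequency stratification of a candidate set."""

    total: int
    n_ge1: int
    n_ge10: int
    n_ge25: int
    n_ge10000: int

    def pct(self, count: int, relative_to: str = "all", decimals: int = 1) -> float:
        denom = self.total if relative_to == "all" else self.n_ge1
        if denom == 0:
            return 0.0
        return round(100.0 * count / denom, decimals)

    @property
    def pct_ge1(self) -> float:
        return self.pct(self.n_ge1)

    @property
    def pct_ge25(self) -> float:
        return self.pct(self.n_ge25)

    @property
    def pct_ge10000(self) -> float:
        return self.pct(self.n_ge10000)


def stratify_df(dfs: Iterable[int | "PhenotypeCandidate"]) -> DfStrata:
    """Counts at the >=1 / >=10 / >=25 / >=10,000 df strata.

    Accepts raw df integers or candidates with populated ``df``.
    """
    values = [d.df if isinstance(d, PhenotypeCandidate) else int(d) for d in dfs]
    return DfStrata(
        total=len(values),
        n_ge1=sum(v >= 1 for v in values),
        n_ge10=sum(v >= 10 for v in values),
        n_ge25=sum(v >= 25 for v in values),
        n_ge10000=sum(v >= 10_000 for v in values),
    )


# ---------------------------------------------------------------------------
# Record export / import


def export_records(
    candidates: Sequence[PhenotypeCandidate],
    rules: Sequence["AssociationRule"],  # noqa: F821 - forward ref to association_miner
    path: str,
    format: str = "xml",
    annotation_date: _dt.date | None = None,
) -> None:
    """Write one database record per candidate (XML or JSON lines).

    Each record carries the term, its accession identifier, the annotation
    date, vocabulary links, associated disorders drawn from the mined rules,
    and literature occurrences.  Rules referencing an unknown normalized
    term raise an export error.
    """
    date = (annotation_date or _dt.date.today()).isoformat()
    by_norm = {c.normalized: c for c in candidates}
    rules_by_norm: dict[str, list] = {c.normalized: [] for c in candidates}
    for rule in rules:
        term = rule.antecedent[2:] if rule.antecedent.startswith("p/") else rule.antecedent
        if term not in by_norm:
            raise ValueError(f"rule references unknown phenotype term: {rule.antecedent!r}")
        rules_by_norm[term].append(rule)

    if format == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for cand in candidates:
                fh.write(json.dumps(_record_dict(cand, rules_by_norm[cand.normalized], date)) + "\n")
        return
    if format != "xml":
        raise ValueError(f"unknown export format: {format!r}")

    root = ET.Element("phenotype_db")
    for cand in candidates:
        rec = ET.SubElement(root, "phenotype", surface=cand.surface)
        ET.SubElement(rec, "term").text = cand.normalized
        ET.SubElement(rec, "identifier").text = cand.pm_id
        ET.SubElement(rec, "annotation_date").text = date
        links = ET.SubElement(rec, "vocabulary_links")
        for concept in cand.quality_concepts:
            ET.SubElement(links, "concept", role="quality").text = concept
        for concept in cand.entity_concepts:
            ET.SubElement(links, "concept", role="entity").text = concept
        disorders = ET.SubElement(rec, "disorders")
        for rule in rules_by_norm[cand.normalized]:
            ET.SubElement(
                disorders,
                "disorder",
                support_count=str(rule.support_count),
                confidence=repr(rule.confidence),
                p_value=repr(rule.p_value),
            ).text = rule.consequent[2:]
        lit = ET.SubElement(rec, "literature", df=str(cand.df))
        for pmid, sent_index, pattern_id in cand.source:
            ET.SubElement(
                lit,
                "occurrence",
                pmid=pmid,
                sent_index=str(sent_index),
                pattern_id=pattern_id,
            )
        for pmid in cand.df_pmids:
            ET.SubElement(lit, "df_pmid").text = pmid
    ET.indent(root)
    ET.ElementTree(root).write(path, encoding="unicode", xml_declaration=True)


def _record_dict(cand: PhenotypeCandidate, rules: list, date: str) -> dict:
    return {
        "term": cand.normalized,
        "identifier": cand.pm_id,
        "annotation_date": date,
        "surface": cand.surface,
        "quality_concepts": cand.quality_concepts,
        "entity_concepts": cand.entity_concepts,
        "disorders": [
            {
                "name": r.consequent[2:],
                "support_count": r.support_count,
                "confidence": r.confidence,
                "p_value": r.p_value,
            }
            for r in rules
        ],
        "df": cand.df,
        "df_pmids": cand.df_pmids,
        "occurrences": [
            {"pmid": p, "sent_index": s, "pattern_id": pid} for p, s, pid in cand.source
        ],
    }


def import_records(path: str, format: str = "xml") -> list[PhenotypeCandidate]:
    """Read back an exported record file into candidates (round-trip of export)."""
    candidates: list[PhenotypeCandidate] = []
    if format == "jsonl":
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                if not line.strip():
                    continue
                d = json.loads(line)
                candidates.append(
                    PhenotypeCandidate(
                        pm_id=d["identifier"],
                        surface=d["surface"],
                        normalized=d["term"],
                        quality_concepts=list(d["quality_concepts"]),
                        entity_concepts=list(d["entity_concepts"]),
                        source=[
                            (o["pmid"], o["sent_index"], o["pattern_id"])
                            for o in d["occurrences"]
                        ],
                        df=d["df"],
                        df_pmids=list(d["df_pmids"]),
                    )
                )
        return candidates
    if format != "xml":
        raise ValueError(f"unknown import format: {format!r}")
    tree = ET.parse(path)
    for rec in tree.getroot().findall("phenotype"):
        lit = rec.find("literature")
        candidates.append(
            PhenotypeCandidate(
                pm_id=rec.findtext("identifier") or "",
                surface=rec.get("surface") or "",
                normalized=rec.findtext("term") or "",
                quality_concepts=[
                    c.text or ""
                    for c in rec.find("vocabulary_links").findall("concept")
                    if c.get("role") == "quality"
                ],
                entity_concepts=[
                    c.text or ""
                    for c in rec.find("vocabulary_links").findall("concept")
                    if c.get("role") == "entity"
                ],
                source=[
                    (o.get("pmid"), int(o.get("sent_index")), o.get("pattern_id"))
                    for o in lit.findall("occurrence")
                ],
                df=int(lit.get("df")),
                df_pmids=[e.text or "" for e in lit.findall("df_pmid")],
            )
        )
    return candidates
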