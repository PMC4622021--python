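"""Association rule mining between phenotypes and disorders over literature co-occurrence.

Transactions are keyed by PMID and hold ``p/``-prefixed phenotype items and
``d/``-prefixed disorder items.  Frequent itemsets are mined level-wise with
support-based pruning (Apriori); rules of the form {phenotype} -> {disorder}
are retained, each with its 2x2 document contingency table and a one-sided
Fisher's exact p-value used for ranking.
"""

from __future__ import annotations

import csv
import math
import statistics
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

from scipy.stats import hypergeom

from .phenotype_extraction import DocumentIndex

__all__ = [
    "DisorderVocabulary",
    "DisorderEntry",
    "TransactionDB",
    "AprioriParams",
    "AssociationRule",
    "load_medic_tsv",
    "build_transactions",
    "min_support_count",
    "frequent_itemsets",
    "apriori",
    "fisher_p",
    "bh_adjust",
    "rank_rules",
    "summarize_rules",
    "write_rules_tsv",
]

PHENOTYPE_PREFIX = "p/"
DISORDER_PREFIX = "d/"


@dataclass
class DisorderEntry:
    canonical_name: str
    omim_id: str
    synonyms: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.canonical_name or not self.omim_id:
            raise ValueError("disorder entries need a canonical name and an OMIM id")
        if any(not s for s in self.synonyms):
            raise ValueError("synonyms must be non-empty strings")

    def all_names(self) -> list[str]:
        return [self.canonical_name, *self.synonyms]


@dataclass
class DisorderVocabulary:
    entries: list[DisorderEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [e.canonical_name for e in self.entries]
        if len(names) != len(set(names)):
            raise ValueError("canonical disorder names must be unique")


def load_medic_tsv(path: str) -> DisorderVocabulary:
    """Load a MEDIC-style disease vocabulary TSV.

    Expected columns: DiseaseName, DiseaseID, AltDiseaseIDs, Synonyms
    (pipe-separated).  Only rows carrying an OMIM identifier (primary or
    alternative) are kept.
    """
    entries: list[DisorderEntry] = []
    with open(path, encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header: list[str] | None = None
        for row in reader:
            if not row or row[0].startswith("#"):
                continue
            if header is None and row[0].strip().lower() == "diseasename":
                header = row
                continue
            name, disease_id = row[0].strip(), row[1].strip() if len(row) > 1 else ""
            alt_ids = row[2].strip() if len(row) > 2 else ""
            synonyms = [s for s in (row[3].split("|") if len(row) > 3 else []) if s]
            omim = ""
            for candidate in [disease_id, *alt_ids.split("|")]:
                if candidate.startswith("OMIM:"):
                    omim = candidate
                    break
            if omim:
                entries.append(DisorderEntry(name, omim, synonyms))
    return DisorderVocabulary(entries)


@dataclass
class TransactionDB:
    """PMID -> set of prefixed items."""

    transactions: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pmid, items in self.transactions.items():
            for item in items:
                if not (
                    item.startswith(PHENOTYPE_PREFIX) or item.startswith(DISORDER_PREFIX)
                ):
                    raise ValueError(f"item {item!r} in {pmid} lacks a p/ or d/ prefix")

    @property
    def n(self) -> int:
        return len(self.transactions)

    def item_support(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for items in self.transactions.values():
            for item in items:
                counts[item] = counts.get(item, 0) + 1
        return counts


@dataclass
class AprioriParams:
    sup: float = 0.000_000_25
    conf: float = 0.1
    minlen: int = 2
    maxlen: int = 2
    target: str = "rules"
    min_phenotype_df: int = 10

    def __post_init__(self) -> None:
        if not (0 < self.sup <= 1):
            raise ValueError("sup must be in (0, 1]")
        if not (0 <= self.conf <= 1):
            raise ValueError("conf must be in [0, 1]")
        if not (2 <= self.minlen <= self.maxlen):
            raise ValueError("need 2 <= minlen <= maxlen")


@dataclass
class AssociationRule:
    """{phenotype} -> {disorder} with document counts and Fisher p-value.

    The 2x2 table is (a, b, c, d) = (both, phenotype only, disorder only,
    neither), summing to the transaction count N.
    """

    antecedent: str
    consequent: str
    support_count: int
    support: float
    confidence: float
    p_value: float
    table: tuple[int, int, int, int]

    def validate(self, n: int) -> None:
        a, b, c, d = self.table
        if a + b + c + d != n:
            raise ValueError("contingency table does not sum to N")
        if self.support_count != a:
            raise ValueError("support_count must equal table a-cell")


class AmbiguousSynonymError(ValueError):
    pass


def build_transactions(
    phenotype_index: DocumentIndex,
    disorder_vocab: DisorderVocabulary,
    disorder_index: DocumentIndex,
    allow_ambiguous_synonyms: bool = False,
) -> TransactionDB:
    """Assemble the PMID-keyed transaction database.

    Each disorder's PMID set is the union over its canonical name and all
    synonyms in the disorder index (so cumulative totals may exceed the
    per-term retrieval cap).  Every PMID seen in either index gets a
    transaction, including single-item ones — they count toward N.
    """
    owner: dict[str, str] = {}
    for entry in disorder_vocab.entries:
        for name in entry.all_names():
            prev = owner.get(name)
            if prev is not None and prev != entry.canonical_name:
                if not allow_ambiguous_synonyms:
                    raise AmbiguousSynonymError(
                        f"synonym {name!r} maps to both {prev!r} and {entry.canonical_name!r}"
                    )
            owner[name] = entry.canonical_name

    transactions: dict[str, set[str]] = {}

    def add(pmid: str, item: str) -> None:
        transactions.setdefault(pmid, set()).add(item)

    for term, pmids in phenotype_index.terms.items():
        for pmid in pmids:
            add(pmid, PHENOTYPE_PREFIX + term)
    for entry in disorder_vocab.entries:
        for name in entry.all_names():
            for pmid in disorder_index.lookup(name):
                add(pmid, DISORDER_PREFIX + entry.canonical_name)
    if allow_ambiguous_synonyms:
        # an ambiguous synonym credits every canonical owner it appeared under
        canonical_by_name: dict[str, list[str]] = {}
        for entry in disorder_vocab.entries:
            for name in entry.all_names():
                canonical_by_name.setdefault(name, []).append(entry.canonical_name)
        for name, owners in canonical_by_name.items():
            if len(owners) > 1:
                for pmid in disorder_index.lookup(name):
                    for canonical in owners:
                        add(pmid, DISORDER_PREFIX + canonical)
    return TransactionDB(transactions)


def min_support_count(sup: float, n: int) -> int:
    """Smallest document count k with k/n >= sup, floored at 1."""
    if n < 1:
        raise ValueError("need at least one transaction")
    return max(1, math.ceil(sup * n))


def frequent_itemsets(
    db: TransactionDB, min_count: int, maxlen: int
) -> dict[frozenset[str], int]:
    """Level-wise frequent itemset mining with candidate pruning."""
    supports: dict[frozenset[str], int] = {}
    singles = {
        frozenset([item]): count
        for item, count in db.item_support().items()
        if count >= min_count
    }
    supports.update(singles)
    current = list(singles)
    k = 1
    tx = list(db.transactions.values())
    while current and k < maxlen:
        k += 1
        # join step: unions of frequent (k-1)-itemsets differing in one item
        items = sorted({i for s in current for i in s})
        candidates: set[frozenset[str]] = set()
        current_set = set(current)
        for base in current:
            for item in items:
                if item in base:
                    continue
                cand = base | {item}
                if len(cand) != k:
                    continue
                # prune: every (k-1)-subset must be frequent
                if all(cand - {i} in current_set for i in cand):
                    candidates.add(cand)
        counts = {c: 0 for c in candidates}
        for t in tx:
            for c in candidates:
                if c <= t:
                    counts[c] += 1
        level = {c: n for c, n in counts.items() if n >= min_count}
        supports.update(level)
        current = list(level)
    return supports


def fisher_p(a: int, b: int, c: int, d: int) -> float:
    """One-sided (over-representation) Fisher's exact p for a 2x2 table.

    p = P(X >= a) where X ~ Hypergeometric(N = a+b+c+d, K = a+b, n = a+c).
    """
    if min(a, b, c, d) < 0:
        raise ValueError("contingency table counts must be non-negative")
    n = a + b + c + d
    if n < 1:
        raise ValueError("empty contingency table")
    return float(hypergeom.sf(a - 1, n, a + b, a + c))


def apriori(db: TransactionDB, params: AprioriParams | None = None) -> list[AssociationRule]:
    """Mine {phenotype} -> {disorder} rules.

    Frequent itemsets are found level-wise up to ``maxlen``; rules are
    generated from frequent 2-itemsets containing one phenotype and one
    disorder item, kept when confidence >= ``conf``, and annotated with the
    2x2 table and Fisher p-value.  Phenotype items with document frequency
    below ``min_phenotype_df`` are excluded.
    """
    params = params or AprioriParams()
    n = db.n
    if n == 0:
        raise ValueError("cannot mine an empty transaction database")
    min_count = min_support_count(params.sup, n)
    supports = frequent_itemsets(db, min_count, params.maxlen)
    item_counts = db.item_support()

    rules: list[AssociationRule] = []
    for itemset, a in supports.items():
        if len(itemset) != 2:
            continue
        phenos = [i for i in itemset if i.startswith(PHENOTYPE_PREFIX)]
        disorders = [i for i in itemset if i.startswith(DISORDER_PREFIX)]
        if len(phenos) != 1 or len(disorders) != 1:
            continue  # post-filter: only {phenotype} -> {disorder}
        p_item, d_item = phenos[0], disorders[0]
        p_total = item_counts[p_item]
        d_total = item_counts[d_item]
        if p_total < params.min_phenotype_df:
            continue
        confidence = a / p_total
        if confidence < params.conf:
            continue
        b = p_total - a
        c = d_total - a
        d_cell = n - a - b - c
        rule = AssociationRule(
            antecedent=p_item,
            consequent=d_item,
            support_count=a,
            support=a / n,
            confidence=confidence,
            p_value=fisher_p(a, b, c, d_cell),
            table=(a, b, c, d_cell),
        )
        rule.validate(n)
        rules.append(rule)
    return rank_rules(rules)


def rank_rules(rules: Iterable[AssociationRule]) -> list[AssociationRule]:
    """Ascending p-value; ties broken by descending support then antecedent."""
    return sorted(
        rules, key=lambda r: (r.p_value, -r.support_count, r.antecedent, r.consequent)
    )


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values (optional extra, not used in ranking)."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank_from_end, idx in enumerate(reversed(order)):
        rank = m - rank_from_end
        running = min(running, p_values[idx] * m / rank)
        adjusted[idx] = running
    return adjusted


def summarize_rules(rules: Sequence[AssociationRule], n: int) -> dict[str, float]:
    """Mean/median/max of support counts and confidences over a rule set."""
    if not rules:
        raise ValueError("cannot summarize an empty rule set")
    counts = [r.support_count for r in rules]
    confs = [r.confidence for r in rules]
    return {
        "n_rules": len(rules),
        "n_transactions": n,
        "mean_support_count": statistics.mean(counts),
        "median_support_count": statistics.median(counts),
        "max_support_count": max(counts),
        "mean_confidence": statistics.mean(confs),
        "median_confidence": statistics.median(confs),
        "max_confidence": max(confs),
    }


def write_rules_tsv(rules: Sequence[AssociationRule], path: str) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(
            ["antecedent", "consequent", "a", "b", "c", "d", "support", "confidence", "p_value"]
        )
        for r in rules:
            a, b, c, d = r.table
            writer.writerow(
                [r.antecedent, r.consequent, a, b, c, d, r.support, r.confidence, r.p_value]
            )
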