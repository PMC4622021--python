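"""Seeded generators for every input the pipeline consumes, with gold labels.

Three generators cover the pipeline end to end without any downloads:

* :func:`gen_lexicons` — toy quality/anatomy/chemical/phenotype/disease
  lexicons, always including the worked-example terms (large, dilated,
  thickened, median; esophagus, nerve) so textbook fragments annotate;
* :func:`gen_corpus` — bracketed sentence trees instantiating the nine
  built-in extraction patterns (positives, each containing a trigger stem)
  plus structurally similar distractors, with exact gold candidate labels;
* :func:`gen_doc_index` — a document index with planted phenotype–disorder
  co-occurrences and exact gold 2x2 contingency tables.

All generators are bit-reproducible given (seed, config).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .concept_annotator import Lexicon, annotate, assemble_semantic_tree
from .corpus_model import ParseTree, SentenceRecord, read_ptb
from .phenotype_extraction import DocumentIndex, normalize_term
from .association_miner import DisorderEntry, DisorderVocabulary

__all__ = [
    "FixtureConfig",
    "GoldLabel",
    "PlantedPair",
    "POSITIVE_TEMPLATES",
    "DISTRACTOR_TEMPLATES",
    "gen_lexicons",
    "gen_corpus",
    "gen_doc_index",
]

#: Ubiquitous background item guaranteeing every document forms a transaction.
BACKGROUND_TERM = "background finding"

POSITIVE_TEMPLATES = [f"p{i}" for i in range(1, 10)]
DISTRACTOR_TEMPLATES = ["d1", "d2", "d3"]

# entity namespace group per pattern column (simple JJ / ADJP / coordination)
_ENTITY_GROUPS = {
    "p1": ("FMA", "RXNORM", "CHEBI", "MA"),
    "p2": ("FMA", "RXNORM", "CHEBI", "MA"),
    "p3": ("FMA", "RXNORM", "CHEBI", "MA"),
    "p4": ("MP", "HP"),
    "p5": ("MP", "HP"),
    "p6": ("MP", "HP"),
    "p7": ("DOID", "ORDO", "OMIM"),
    "p8": ("DOID", "ORDO", "OMIM"),
    "p9": ("DOID", "ORDO", "OMIM"),
}

#: PATO adjectives whose surface form carries a built-in trigger stem.
_TRIGGER_PATO = [
    "abnormal",
    "atypical",
    "unusual",
    "irregular",
    "aberrant",
    "defective",
    "anomalous",
    "unhealthy",
    "inadequate",
    "inactive",
    "characteristic",
]

#: PATO adjectives without a trigger stem (worked examples first).
_PLAIN_PATO = ["large", "dilated", "thickened", "median"]

_WORKED_ENTITIES = {"FMA": ["esophagus", "nerve"]}

#: Words deliberately absent from every lexicon.
_UNANNOTATED_NOUNS = ["finding", "report", "series", "cohort", "figure", "study"]
_UNANNOTATED_ADJS = ["solid", "green", "recent", "present"]


@dataclass
class FixtureConfig:
    seed: int = 42
    n_sentences: int = 200
    pattern_mix: dict[str, float] = field(
        default_factory=lambda: {
            **{t: 1.0 for t in POSITIVE_TEMPLATES},
            **{t: 1.0 for t in DISTRACTOR_TEMPLATES},
        }
    )
    lexicon_sizes: dict[str, int] = field(
        default_factory=lambda: {
            "PATO": 20,
            "FMA": 8,
            "RXNORM": 4,
            "CHEBI": 4,
            "MA": 4,
            "MP": 6,
            "HP": 6,
            "DOID": 4,
            "ORDO": 4,
            "OMIM": 4,
        }
    )
    n_docs: int = 5000
    n_planted_pairs: int = 5
    baseline_cooccur_prob: float = 0.002
    planted_cooccur_prob: float = 0.02
    sentences_per_doc: int = 3

    def __post_init__(self) -> None:
        for p in (self.baseline_cooccur_prob, self.planted_cooccur_prob):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.planted_cooccur_prob <= self.baseline_cooccur_prob:
            raise ValueError("planted_cooccur_prob must exceed baseline_cooccur_prob")
        if min(self.n_sentences, self.n_docs, self.n_planted_pairs) < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class GoldLabel:
    """What extraction should produce for one generated sentence."""

    doc_id: str
    sent_index: int
    template: str
    surfaces: list[str]  # expected candidate surface forms ([] for distractors)
    pattern_ids: list[str]


@dataclass
class PlantedPair:
    phenotype: str
    disorder: str
    table: tuple[int, int, int, int]  # gold (a, b, c, d), sums to n_docs


def gen_lexicons(config: FixtureConfig) -> list[Lexicon]:
    """Deterministic toy lexicons; namespaces with size 0 are omitted."""
    rng = random.Random(config.seed * 7919 + 1)
    lexicons: list[Lexicon] = []
    counter = 0
    for ns, size in sorted(config.lexicon_sizes.items()):
        if size <= 0:
            continue
        lex = Lexicon(ns)
        seeds: list[str] = []
        if ns == "PATO":
            seeds = _TRIGGER_PATO + _PLAIN_PATO
        else:
            seeds = list(_WORKED_ENTITIES.get(ns, []))
        for term in seeds[: max(size, len(seeds))]:
            counter += 1
            lex.add(term, f"{ns}:{7000000 + counter:07d}")
        i = 0
        while len(lex.entries) < size:
            counter += 1
            lex.add(f"{ns.lower()}term{i}", f"{ns}:{7000000 + counter:07d}")
            i += 1
        lexicons.append(lex)
    # shuffle order deterministically; annotation is order-independent per namespace
    rng.shuffle(lexicons)
    return lexicons


def _pato_pools(lexicons: Sequence[Lexicon]) -> tuple[list[str], list[str]]:
    pato = next((l for l in lexicons if l.namespace == "PATO"), None)
    if pato is None:
        raise ValueError("fixture corpus requires a PATO lexicon")
    trigger = [t for t in pato.entries if t in _TRIGGER_PATO]
    plain = [t for t in pato.entries if t not in _TRIGGER_PATO]
    if not trigger:
        raise ValueError("PATO lexicon has no trigger-bearing adjectives")
    return trigger, plain or trigger


def _entity_pool(lexicons: Sequence[Lexicon], group: tuple[str, ...]) -> list[str]:
    terms = []
    for lex in lexicons:
        if lex.namespace in group:
            terms.extend(t for t in lex.entries if " " not in t)
    if not terms:
        raise ValueError(f"no lexicon entries for entity group {group}")
    return sorted(terms)


def _build_template(
    template: str,
    rng: random.Random,
    lexicons: Sequence[Lexicon],
) -> tuple[str, list[str]]:
    """Return (bracketed tree, gold surfaces) for one sentence."""
    trigger_adjs, plain_adjs = _pato_pools(lexicons)
    if template in _ENTITY_GROUPS:
        entities = _entity_pool(lexicons, _ENTITY_GROUPS[template])
        noun = rng.choice(entities)
        kind = {"1": "simple", "2": "adjp", "4": "simple", "5": "adjp",
                "7": "simple", "8": "adjp", "3": "coord", "6": "coord",
                "9": "coord"}[template[1]]
        if kind == "simple":
            adj = rng.choice(trigger_adjs)
            np_str = f"(NP (DT the) (JJ {adj}) (NN {noun}))"
            surface = f"the {adj} {noun}"
        elif kind == "adjp":
            adj = rng.choice(plain_adjs)
            np_str = f"(NP (DT an) (ADJP (RB abnormally) (JJ {adj})) (NN {noun}))"
            surface = f"an abnormally {adj} {noun}"
        else:  # coordination
            adj = rng.choice(trigger_adjs)
            filler_noun = rng.choice(_UNANNOTATED_NOUNS)
            filler_adj = rng.choice(_UNANNOTATED_ADJS)
            np_str = (
                f"(NP (NP (JJ {adj}) (NN {filler_noun})) (CC and) "
                f"(NP (JJ {filler_adj}) (NN {noun})))"
            )
            surface = f"{adj} {filler_noun} and {filler_adj} {noun}"
        tree = f"(S {np_str} (VP (VBD was) (VBN observed)) (. .))"
        return tree, [surface]
    if template == "d1":
        # incomplete phrase: quality without an annotated entity
        adj = rng.choice(trigger_adjs)
        noun = rng.choice(_UNANNOTATED_NOUNS)
        return (
            f"(S (NP (DT the) (JJ {adj}) (NN {noun})) (VP (VBD persisted)) (. .))",
            [],
        )
    if template == "d2":
        # entity without a quality adjective; trigger sits outside any NP
        entities = _entity_pool(lexicons, ("FMA", "MA", "HP", "MP", "DOID"))
        noun = rng.choice(entities)
        adj = rng.choice(_UNANNOTATED_ADJS)
        return (
            f"(S (NP (DT the) (JJ {adj}) (NN {noun})) "
            f"(VP (VBD appeared) (ADJP (JJ abnormal))) (. .))",
            [],
        )
    if template == "d3":
        # structure description with no trigger stem at all
        return (
            "(S (NP (DT a) (NN protein) (NN structure)) (VP (VBD bound)) (. .))",
            [],
        )
    raise ValueError(f"unknown template {template!r}")


def gen_corpus(
    config: FixtureConfig, lexicons: Sequence[Lexicon]
) -> tuple[list[tuple[SentenceRecord, ParseTree]], list[GoldLabel]]:
    """Generate annotated sentence trees plus exact gold labels.

    Returns (record, annotated_tree) pairs and one :class:`GoldLabel` per
    sentence; distractor sentences carry empty gold surface lists.
    """
    rng = random.Random(config.seed * 7919 + 2)
    templates = sorted(config.pattern_mix)
    weights = [config.pattern_mix[t] for t in templates]
    out: list[tuple[SentenceRecord, ParseTree]] = []
    gold: list[GoldLabel] = []
    for i in range(config.n_sentences):
        template = rng.choices(templates, weights=weights, k=1)[0]
        tree_str, surfaces = _build_template(template, rng, lexicons)
        tree = read_ptb(tree_str)
        tokens = tree.yield_tokens()
        record = SentenceRecord(
            doc_id=str(9_000_000 + i // max(config.sentences_per_doc, 1)),
            sent_index=i % max(config.sentences_per_doc, 1),
            text=" ".join(tokens),
            tokens=tokens,
            tree=tree,
        )
        annotated = assemble_semantic_tree(tree, annotate(tokens, lexicons))
        out.append((record, annotated))
        gold.append(
            GoldLabel(
                doc_id=record.doc_id,
                sent_index=record.sent_index,
                template=template,
                surfaces=surfaces,
                pattern_ids=[template] if template in _ENTITY_GROUPS else [],
            )
        )
    return out, gold


def _default_disorders(n: int) -> DisorderVocabulary:
    entries = []
    for i in range(n):
        entries.append(
            DisorderEntry(
                canonical_name=f"syndrome {i} type a",
                omim_id=f"OMIM:{600000 + i}",
                synonyms=[f"syndrome {i} disease", f"disorder {i} variant"],
            )
        )
    return DisorderVocabulary(entries)


def gen_doc_index(
    config: FixtureConfig,
    phenotype_terms: Sequence[str],
    disorder_vocab: DisorderVocabulary | None = None,
    n_disorders: int = 10,
) -> tuple[DocumentIndex, DocumentIndex, DisorderVocabulary, list[PlantedPair]]:
    """Generate phenotype/disorder document indexes with planted associations.

    Every document contains each term independently with the baseline
    probability; for each planted (phenotype, disorder) pair the joint
    occurrence is boosted by an OR-ed Bernoulli(planted_cooccur_prob)
    indicator.  A ubiquitous background phenotype term keeps every document
    in the transaction universe so gold tables sum to ``n_docs`` exactly.

    Disorder hits are partitioned across the canonical name and synonyms to
    exercise synonym unification; per-term lists are capped at the index cap.
    """
    if config.n_docs < 1:
        raise ValueError("n_docs must be >= 1")
    phenotype_terms = [normalize_term(t) for t in phenotype_terms]
    if len(set(phenotype_terms)) != len(phenotype_terms):
        raise ValueError("phenotype terms must be unique after normalization")
    vocab = disorder_vocab or _default_disorders(n_disorders)
    rng = np.random.default_rng(config.seed * 7919 + 3)
    n_docs = config.n_docs
    n_p = len(phenotype_terms)
    n_d = len(vocab.entries)
    pmids = np.array([str(1_000_000 + j) for j in range(n_docs)])

    p_occ = rng.random((n_p, n_docs)) < config.baseline_cooccur_prob
    d_occ = rng.random((n_d, n_docs)) < config.baseline_cooccur_prob

    n_pairs = min(config.n_planted_pairs, n_p, n_d)
    planted_idx = [(i, i) for i in range(n_pairs)]
    for pi, di in planted_idx:
        joint = rng.random(n_docs) < config.planted_cooccur_prob
        p_occ[pi] |= joint
        d_occ[di] |= joint

    planted: list[PlantedPair] = []
    for pi, di in planted_idx:
        a = int(np.sum(p_occ[pi] & d_occ[di]))
        b = int(np.sum(p_occ[pi] & ~d_occ[di]))
        c = int(np.sum(~p_occ[pi] & d_occ[di]))
        planted.append(
            PlantedPair(
                phenotype=phenotype_terms[pi],
                disorder=vocab.entries[di].canonical_name,
                table=(a, b, c, n_docs - a - b - c),
            )
        )

    pheno_terms: dict[str, list[str]] = {
        term: list(pmids[p_occ[i]]) for i, term in enumerate(phenotype_terms)
    }
    pheno_terms[BACKGROUND_TERM] = list(pmids)
    pheno_index = DocumentIndex(pheno_terms)

    disorder_terms: dict[str, list[str]] = {}
    for i, entry in enumerate(vocab.entries):
        hits = list(pmids[d_occ[i]])
        names = entry.all_names()
        k = int(rng.integers(2, min(4, len(names)) + 1))
        buckets: dict[str, list[str]] = {name: [] for name in names[:k]}
        for j, pmid in enumerate(hits):
            buckets[names[j % k]].append(pmid)
        disorder_terms.update(buckets)
    disorder_index = DocumentIndex(disorder_terms)
    return pheno_index, disorder_index, vocab, planted
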