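"""Shared fixtures: seeded random tree generators and small corpora."""

from __future__ import annotations

import random

import pytest

from eqminer.corpus_model import ParseTree

# concept pools used when decorating random trees with SEM nodes
QUALITY_CONCEPTS = ["PATO:0000460", "PATO:0000574", "PATO:0001555"]
ENTITY_CONCEPTS = [
    "FMA:7131",
    "FMA:65132",
    "MA:0000072",
    "CHEBI:15377",
    "RXNORM:1191",
    "HP:0001627",
    "MP:0000266",
    "DOID:9352",
    "ORDO:558",
    "OMIM:154700",
]
OTHER_CONCEPTS = ["GO:0008150", "SNOMEDCT:22298006"]

_WORDS = ["alpha", "beta", "gamma", "delta", "organ", "tissue", "cells", "and",
          "the", "a", "signal", "defect"]
_PHRASE_LABELS = ["NP", "VP", "ADJP", "PP", "S"]
_POS_LABELS = ["DT", "JJ", "NN", "NNS", "NNP", "CC", "RB", "VBD", "IN"]


def random_tree(rng: random.Random, max_nodes: int = 40, sem_prob: float = 0.4) -> ParseTree:
    """A random phrase-structure tree of at most ``max_nodes`` nodes.

    Preterminals optionally carry SEM children whose leaf is a ``;``-joined
    concept list, so extraction patterns have something to match.
    """
    while True:
        tree = _random_tree_once(rng, max_nodes, sem_prob)
        if count_nodes(tree) <= max_nodes:
            return tree


def _random_tree_once(rng: random.Random, max_nodes: int, sem_prob: float) -> ParseTree:
    budget = [rng.randint(8, max_nodes - 4)]

    def take(n: int) -> bool:
        if budget[0] >= n:
            budget[0] -= n
            return True
        return False

    def gen_preterminal() -> ParseTree:
        pos = rng.choice(_POS_LABELS)
        node = ParseTree(pos, [ParseTree(rng.choice(_WORDS))])
        if rng.random() < sem_prob and take(2):
            pool = rng.choice([QUALITY_CONCEPTS, ENTITY_CONCEPTS, OTHER_CONCEPTS])
            k = rng.randint(1, 2)
            concepts = sorted(set(rng.choices(pool, k=k)))
            node.children.append(ParseTree("SEM", [ParseTree(";".join(concepts))]))
        return node

    def sem_child(pool) -> ParseTree:
        concepts = sorted(set(rng.choices(pool, k=rng.randint(1, 2))))
        return ParseTree("SEM", [ParseTree(";".join(concepts))])

    def gen_motif() -> ParseTree:
        """An NP shaped like (or almost like) the extraction patterns."""
        quality = ParseTree("JJ", [ParseTree(rng.choice(_WORDS))])
        if rng.random() < 0.8:
            quality.children.append(sem_child(QUALITY_CONCEPTS))
        noun_label = rng.choice(["NN", "NNS", "NN", "NP"])
        noun = ParseTree(noun_label, [ParseTree(rng.choice(_WORDS))])
        if rng.random() < 0.8:
            noun.children.append(
                sem_child(rng.choice([ENTITY_CONCEPTS, OTHER_CONCEPTS]))
            )
        shape = rng.random()
        take(8)
        if shape < 0.4:  # plain JJ sister
            kids = [ParseTree("DT", [ParseTree("the")]), quality]
            if rng.random() < 0.3:
                kids.append(ParseTree("JJ", [ParseTree(rng.choice(_WORDS))]))
            kids.append(noun)
            return ParseTree("NP", kids)
        if shape < 0.7:  # ADJP-wrapped
            adjp = ParseTree("ADJP", [ParseTree("RB", [ParseTree("very")]), quality])
            return ParseTree("NP", [adjp, noun])
        # coordination, sometimes with the CC misplaced
        left = ParseTree("NP", [quality, ParseTree("NN", [ParseTree(rng.choice(_WORDS))])])
        right = ParseTree("NP", [noun])
        cc = ParseTree("CC", [ParseTree("and")])
        order = rng.choice([[left, cc, right], [left, right, cc], [cc, left, right]])
        return ParseTree("NP", order)

    def gen_node(depth: int) -> ParseTree:
        if depth < 3 and budget[0] >= 8 and rng.random() < 0.4:
            return gen_motif()
        if depth >= 4 or budget[0] < 4 or rng.random() < 0.35:
            take(2)
            return gen_preterminal()
        take(1)
        label = rng.choice(_PHRASE_LABELS)
        n_children = rng.randint(1, 3)
        children = [gen_node(depth + 1) for _ in range(n_children)]
        return ParseTree(label, children)

    take(1)
    return ParseTree("S", [gen_node(1) for _ in range(rng.randint(1, 3))])


def count_nodes(tree: ParseTree) -> int:
    return 1 + sum(count_nodes(c) for c in tree.children)


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20240917)


@pytest.fixture(scope="session")
def default_fixture_setup():
    """Default-config lexicons, corpus and gold labels, generated once."""
    from eqminer.synthetic_fixtures import FixtureConfig, gen_corpus, gen_lexicons

    config = FixtureConfig(seed=42, n_sentences=300)
    lexicons = gen_lexicons(config)
    corpus, gold = gen_corpus(config, lexicons)
    return config, lexicons, corpus, gold
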