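"""Tests for transaction building, Apriori mining, Fisher ranking and summaries."""

import math
import random
from fractions import Fraction
from itertools import combinations

import pytest

from eqminer.association_miner import (
    AmbiguousSynonymError,
    AprioriParams,
    AssociationRule,
    DisorderEntry,
    DisorderVocabulary,
    TransactionDB,
    apriori,
    bh_adjust,
    build_transactions,
    fisher_p,
    frequent_itemsets,
    load_medic_tsv,
    min_support_count,
    rank_rules,
    summarize_rules,
)
from eqminer.phenotype_extraction import DocumentIndex


def oracle_rules(db: TransactionDB, params: AprioriParams):
    """Brute-force pair enumeration: count every (p, d) pair over the raw
    transactions and apply the thresholds directly."""
    n = db.n
    min_count = max(1, math.ceil(params.sup * n))
    items = sorted({i for t in db.transactions.values() for i in t})
    counts = {i: sum(i in t for t in db.transactions.values()) for i in items}
    rules = {}
    for p_item in (i for i in items if i.startswith("p/")):
        if counts[p_item] < params.min_phenotype_df:
            continue
        for d_item in (i for i in items if i.startswith("d/")):
            a = sum(
                p_item in t and d_item in t for t in db.transactions.values()
            )
            if a < min_count or counts[p_item] < min_count or counts[d_item] < min_count:
                continue
            conf = a / counts[p_item]
            if conf < params.conf:
                continue
            rules[(p_item, d_item)] = (a, a / n, conf)
    return rules


def random_db(rng: random.Random) -> TransactionDB:
    n_items = rng.randint(2, 15)
    items = [f"p/t{i}" if rng.random() < 0.5 else f"d/D{i}" for i in range(n_items)]
    n_tx = rng.randint(1, 200)
    tx = {}
    for j in range(n_tx):
        k = rng.randint(0, min(6, n_items))
        tx[str(j)] = set(rng.sample(items, k))
    return TransactionDB(tx)


class TestBuildTransactions:
    def test_synonym_unification(self):
        vocab = DisorderVocabulary([
            DisorderEntry("Leopard syndrome", "OMIM:151100",
                          ["Gorlin syndrome", "Cardiocutaneous syndrome"]),
        ])
        didx = DocumentIndex({
            "Leopard syndrome": ["1", "2"],
            "Gorlin syndrome": ["2", "3"],
            "Cardiocutaneous syndrome": ["4"],
        })
        db = build_transactions(DocumentIndex({}), vocab, didx)
        for pmid in ["1", "2", "3", "4"]:
            assert "d/Leopard syndrome" in db.transactions[pmid]
        assert db.n == 4

    def test_empty_refuses_mining(self):
        db = build_transactions(DocumentIndex({}), DisorderVocabulary([]), DocumentIndex({}))
        assert db.n == 0
        with pytest.raises(ValueError):
            apriori(db)

    def test_marfan_shaped_transaction(self):
        phenos = {f"abnormal sign {i}": ["18852161"] for i in range(5)}
        vocab = DisorderVocabulary([DisorderEntry("Marfan Syndrome", "OMIM:154700")])
        didx = DocumentIndex({"Marfan Syndrome": ["18852161"]})
        db = build_transactions(DocumentIndex(phenos), vocab, didx)
        assert len(db.transactions["18852161"]) == 6

    def test_single_item_transactions_count_toward_n(self):
        pidx = DocumentIndex({"abnormal gait": ["1", "2"]})
        vocab = DisorderVocabulary([DisorderEntry("X disease", "OMIM:1")])
        didx = DocumentIndex({"X disease": ["2", "3"]})
        db = build_transactions(pidx, vocab, didx)
        assert db.n == 3
        assert db.transactions["1"] == {"p/abnormal gait"}

    def test_ambiguous_synonym_raises(self):
        vocab = DisorderVocabulary([
            DisorderEntry("A", "OMIM:1", ["shared name"]),
            DisorderEntry("B", "OMIM:2", ["shared name"]),
        ])
        with pytest.raises(AmbiguousSynonymError, match="shared name"):
            build_transactions(DocumentIndex({}), vocab, DocumentIndex({}))

    def test_ambiguous_synonym_override_assigns_both(self):
        vocab = DisorderVocabulary([
            DisorderEntry("A", "OMIM:1", ["shared name"]),
            DisorderEntry("B", "OMIM:2", ["shared name"]),
        ])
        didx = DocumentIndex({"shared name": ["7"]})
        db = build_transactions(DocumentIndex({}), vocab, didx,
                                allow_ambiguous_synonyms=True)
        assert db.transactions["7"] == {"d/A", "d/B"}

    def test_item_prefix_enforced(self):
        with pytest.raises(ValueError):
            TransactionDB({"1": {"unprefixed"}})


class TestMinSupportCount:
    def test_paper_scale_conversion(self):
        assert min_support_count(0.000_000_25, 7_000_000) == 2

    def test_floor_at_one(self):
        assert min_support_count(0.0, 1000) == 1

    def test_ceiling(self):
        assert min_support_count(0.5, 5) == 3

    def test_definition_smallest_k(self, rng):
        for _ in range(200):
            n = rng.randint(1, 10_000)
            sup = rng.random()
            k = min_support_count(sup, n)
            assert k / n >= sup or k == 1
            if k > 1:
                assert (k - 1) / n < sup


class TestApriori:
    def test_spec_example_five_transactions(self):
        db = TransactionDB({
            "1": {"p/A", "d/X"}, "2": {"p/A", "d/X"}, "3": {"p/A"},
            "4": {"d/X"}, "5": {"p/B"},
        })
        rules = apriori(db, AprioriParams(sup=0.2, conf=0.1, min_phenotype_df=1))
        assert len(rules) == 1
        r = rules[0]
        assert (r.antecedent, r.consequent) == ("p/A", "d/X")
        assert r.support_count == 2
        assert r.support == pytest.approx(0.4)
        assert r.confidence == pytest.approx(2 / 3)
        assert r.table == (2, 1, 1, 1)

    def test_conf_one_excludes_all(self):
        db = TransactionDB({
            "1": {"p/A", "d/X"}, "2": {"p/A", "d/X"}, "3": {"p/A"},
            "4": {"d/X"}, "5": {"p/B"},
        })
        assert apriori(db, AprioriParams(sup=0.2, conf=1.0, min_phenotype_df=1)) == []

    def test_oracle_equivalence_200_random_dbs(self):
        rng = random.Random(777)
        for trial in range(200):
            db = random_db(rng)
            if db.n == 0:
                continue
            params = AprioriParams(
                sup=rng.choice([1e-9, 0.01, 0.05, 0.2]),
                conf=rng.choice([0.0, 0.1, 0.5]),
                min_phenotype_df=rng.choice([1, 2]),
            )
            got = {
                (r.antecedent, r.consequent): (r.support_count, r.support, r.confidence)
                for r in apriori(db, params)
            }
            expected = oracle_rules(db, params)
            assert got.keys() == expected.keys(), f"trial {trial}"
            for key, (a, sup, conf) in expected.items():
                ga, gsup, gconf = got[key]
                assert ga == a
                assert gsup == pytest.approx(sup)
                assert gconf == pytest.approx(conf)

    def test_rule_identity_confidence_times_pa(self):
        rng = random.Random(31)
        db = random_db(rng)
        counts = db.item_support()
        for r in apriori(db, AprioriParams(sup=1e-9, conf=0.0, min_phenotype_df=1)):
            p_antecedent = counts[r.antecedent] / db.n
            assert r.confidence * p_antecedent == pytest.approx(r.support)
            a, b, c, d = r.table
            assert a + b + c + d == db.n

    def test_anti_monotonicity(self):
        rng = random.Random(13)
        for _ in range(30):
            db = random_db(rng)
            if db.n == 0:
                continue
            min_count = 2
            freq = frequent_itemsets(db, min_count, maxlen=2)
            singles = {s for s in freq if len(s) == 1}
            for itemset in freq:
                if len(itemset) == 2:
                    for item in itemset:
                        assert frozenset([item]) in singles

    def test_levelwise_maxlen3_vs_enumeration(self):
        rng = random.Random(4242)
        for _ in range(40):
            db = random_db(rng)
            if db.n == 0:
                continue
            min_count = rng.randint(1, 4)
            got = frequent_itemsets(db, min_count, maxlen=3)
            items = sorted({i for t in db.transactions.values() for i in t})
            expected = {}
            for size in (1, 2, 3):
                for combo in combinations(items, size):
                    s = frozenset(combo)
                    count = sum(s <= t for t in db.transactions.values())
                    if count >= min_count:
                        expected[s] = count
            assert got == expected


def oracle_fisher(a, b, c, d):
    """Exact-fraction hypergeometric tail: P(X >= a) with fixed margins."""
    n = a + b + c + d
    row = a + b
    col = a + c
    denom = math.comb(n, col)
    total = Fraction(0)
    for k in range(a, min(row, col) + 1):
        total += Fraction(math.comb(row, k) * math.comb(n - row, col - k), denom)
    return float(total)


class TestFisherP:
    def test_no_cooccurrence_is_maximal(self):
        p0 = fisher_p(0, 5, 5, 90)
        assert p0 > 0.999 or p0 == pytest.approx(1.0, abs=1e-3)
        assert p0 >= fisher_p(3, 2, 2, 93)

    def test_perfect_overlap_closed_form(self):
        assert fisher_p(5, 0, 0, 5) == pytest.approx(1 / math.comb(10, 5), abs=1e-15)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            fisher_p(-1, 1, 1, 1)

    def test_enumeration_oracle_1000_tables(self):
        rng = random.Random(2024)
        for _ in range(1000):
            n = rng.randint(1, 30)
            a = rng.randint(0, n)
            b = rng.randint(0, n - a)
            c = rng.randint(0, n - a - b)
            d = n - a - b - c
            assert fisher_p(a, b, c, d) == pytest.approx(
                oracle_fisher(a, b, c, d), abs=1e-12
            )

    def test_monotone_in_a_with_fixed_margins(self):
        # shift mass along the diagonal: a+b, a+c fixed
        row, col, n = 10, 8, 40
        last = 1.1
        for a in range(0, min(row, col) + 1):
            b, c = row - a, col - a
            d = n - a - b - c
            if d < 0:
                break
            p = fisher_p(a, b, c, d)
            assert p <= last + 1e-12
            last = p


class TestRankAndSummarize:
    def make(self, p, support_count=5, antecedent="p/a"):
        return AssociationRule(antecedent, "d/X", support_count,
                               0.1, 0.5, p, (support_count, 1, 1, 1))

    def test_ascending_p(self):
        rules = [self.make(0.5), self.make(0.001), self.make(0.02)]
        assert [r.p_value for r in rank_rules(rules)] == [0.001, 0.02, 0.5]

    def test_tie_break_support(self):
        rules = [self.make(0.01, support_count=3), self.make(0.01, support_count=10)]
        assert [r.support_count for r in rank_rules(rules)] == [10, 3]

    def test_tie_break_antecedent(self):
        rules = [self.make(0.01, antecedent="p/b"), self.make(0.01, antecedent="p/a")]
        assert [r.antecedent for r in rank_rules(rules)] == ["p/a", "p/b"]

    def test_summary_single_rule(self):
        s = summarize_rules([self.make(0.5, support_count=7)], n=100)
        assert s["mean_support_count"] == s["median_support_count"] == 7
        assert s["max_support_count"] == 7

    def test_summary_two_rules(self):
        rules = [self.make(0.1, support_count=10), self.make(0.2, support_count=20)]
        s = summarize_rules(rules, n=50)
        assert s["mean_support_count"] == 15
        assert s["median_support_count"] == 15

    def test_summary_oracle_recomputation(self, rng):
        rules = [self.make(rng.random(), support_count=rng.randint(1, 50))
                 for _ in range(25)]
        s = summarize_rules(rules, n=1000)
        counts = sorted(r.support_count for r in rules)
        assert s["mean_support_count"] == pytest.approx(sum(counts) / 25)
        assert s["median_support_count"] == counts[12]
        assert s["max_confidence"] == max(r.confidence for r in rules)

    def test_summary_empty_refused(self):
        with pytest.raises(ValueError):
            summarize_rules([], n=10)

    def test_bh_adjust_monotone_and_bounded(self, rng):
        ps = [rng.random() for _ in range(20)]
        adj = bh_adjust(ps)
        assert all(0 <= q <= 1 for q in adj)
        order = sorted(range(20), key=lambda i: ps[i])
        assert all(adj[order[i]] <= adj[order[i + 1]] + 1e-12 for i in range(19))


class TestMedicLoader:
    def test_omim_filter_and_synonyms(self, tmp_path):
        p = tmp_path / "medic.tsv"
        p.write_text(
            "DiseaseName\tDiseaseID\tAltDiseaseIDs\tSynonyms\n"
            "Marfan Syndrome\tMESH:D008382\tOMIM:154700\tMarfan's syndrome|MFS\n"
            "Some MeSH-only disease\tMESH:D000001\t\tAlias\n"
            "Direct OMIM disease\tOMIM:100000\t\t\n"
        )
        vocab = load_medic_tsv(str(p))
        names = [e.canonical_name for e in vocab.entries]
        assert names == ["Marfan Syndrome", "Direct OMIM disease"]
        assert vocab.entries[0].synonyms == ["Marfan's syndrome", "MFS"]
        assert vocab.entries[0].omim_id == "OMIM:154700"
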