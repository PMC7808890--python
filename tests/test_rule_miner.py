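import math

import numpy as np
import pytest

from cbar.data_model import Dataset, Transaction, build_bitmap_index
from cbar.rule_miner import (
    Accept,
    ConfidenceCounter,
    MiningError,
    MiningParams,
    ParameterError,
    Reject,
    Rule,
    confidence_with_early_stop,
    mine_class_rules,
    mine_frequent_itemsets,
    rules_from_jsonl,
    rules_to_jsonl,
    sample_dataset,
)
from conftest import random_dataset
from oracles import brute_force_mine, full_count_confidence_decision


class TestFrequentItemsets:
    def test_fixture_a_commonalities(self, fixture_a_dataset):
        s_w = fixture_a_dataset.s_w(1)
        out = dict(mine_frequent_itemsets(s_w, 0.5, 2, ["A", "B", "C"]))
        assert out == {
            frozenset({"A"}): 0.75,
            frozenset({"B"}): 0.75,
            frozenset({"A", "B"}): 0.5,
        }

    def test_threshold_one_yields_nothing_on_fixture(self, fixture_a_dataset):
        assert mine_frequent_itemsets(fixture_a_dataset.s_w(1), 1.0, 3, ["A", "B", "C"]) == []

    def test_l_max_one_gives_singletons_only(self, fixture_a_dataset):
        out = mine_frequent_itemsets(fixture_a_dataset.s_w(1), 0.1, 1, ["A", "B", "C"])
        assert all(len(s) == 1 for s, _ in out)

    def test_empty_s_w_is_error(self):
        with pytest.raises(MiningError, match="no instances"):
            mine_frequent_itemsets([], 0.5, 2, ["A"])

    def test_commonality_antimonotone_on_random_data(self):
        rng = np.random.default_rng(5)
        ds = random_dataset(rng, n_max=120, n_items_max=8)
        out = dict(mine_frequent_itemsets(ds.s_w(1), 0.05, 3, ds.vocabulary_ids()))
        for lhs, comm in out.items():
            for lhs2, comm2 in out.items():
                if lhs < lhs2:
                    assert comm2 <= comm


class TestEarlyStop:
    def test_fixture_accept_at_the_bound(self, fixture_a_index):
        out = confidence_with_early_stop({"A"}, 1, fixture_a_index, 0.5)
        assert out == Accept(confidence=0.5, l_w=3, l_not_w=3)

    def test_fixture_reject_after_second_negative_match(self, fixture_a_index):
        # l_w=1 so T_l=1; C appears in negative rows 5 and 7: stop at row 7,
        # i.e. after scanning 3 of the 6 negative rows (rows 8-10 untouched)
        out = confidence_with_early_stop({"C"}, 1, fixture_a_index, 0.5)
        assert out == Reject(rows_scanned=3)

    def test_zero_positive_matches_rejects_immediately(self, fixture_a_dataset):
        idx = build_bitmap_index(fixture_a_dataset, vocabulary=["A", "B", "C", "Z"])
        assert confidence_with_early_stop({"Z"}, 1, idx, 0.5) == Reject(rows_scanned=0)

    def test_t_l_formula(self):
        assert ConfidenceCounter(l_w=5).t_l(0.2) == pytest.approx(20.0)

    def test_agrees_with_full_count_on_random_triples(self):
        rng = np.random.default_rng(77)
        c_grid = [0.2, 0.25, 1 / 3, 0.4, 0.5, 0.6, 2 / 3, 0.75, 0.9, 1.0]
        checked = 0
        while checked < 1000:
            ds = random_dataset(rng, n_max=120, n_items_max=8)
            vocab = sorted({i for t in ds.transactions for i in t.items}) or ["i0"]
            idx = build_bitmap_index(ds, vocabulary=vocab)
            for _ in range(20):
                size = int(rng.integers(1, min(3, len(vocab)) + 1))
                itemset = frozenset(rng.choice(vocab, size=size, replace=False))
                c_min = float(rng.choice(c_grid))
                got = confidence_with_early_stop(itemset, 1, idx, c_min)
                accepted, conf, l_w, l_nw = full_count_confidence_decision(itemset, 1, ds, c_min)
                if accepted:
                    assert got == Accept(confidence=conf, l_w=l_w, l_not_w=l_nw)
                else:
                    assert isinstance(got, Reject)
                checked += 1

    def test_decision_invariant_to_row_order(self, fixture_a_dataset):
        perm = list(fixture_a_dataset.transactions)[::-1]
        shuffled = Dataset(tuple(perm), interesting_values=(1,))
        idx = build_bitmap_index(shuffled)
        out = confidence_with_early_stop({"C"}, 1, idx, 0.5)
        assert isinstance(out, Reject)  # only rows_scanned may differ


class TestMineClassRules:
    def test_fixture_a_exact_rule_set(self, fixture_a_dataset):
        params = MiningParams(m_min=0.5, c_min=0.5, l_max=2)
        rules = mine_class_rules(fixture_a_dataset, 1, params)
        stats = {r.lhs: (r.confidence, r.commonality, r.support) for r in rules}
        assert stats == {
            frozenset({"A"}): (0.5, 0.75, 0.3),
            frozenset({"B"}): (0.6, 0.75, 0.3),
            frozenset({"A", "B"}): (2 / 3, 0.5, 0.2),
        }

    def test_no_positive_instances_is_error(self):
        ds = Dataset(
            (Transaction(1, {"A"}, 0), Transaction(2, {"B"}, 0)), interesting_values=(1,)
        )
        with pytest.raises(MiningError):
            mine_class_rules(ds, 1, MiningParams(m_min=0.5))

    def test_support_identity_holds_for_every_mined_rule(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            ds = random_dataset(rng, n_max=150, n_items_max=9)
            rules = mine_class_rules(ds, 1, MiningParams(m_min=0.05, c_min=0.3, l_max=3))
            n_w, n = len(ds.s_w(1)), len(ds)
            for r in rules:
                assert r.support == pytest.approx(r.commonality * n_w / n, abs=1e-12)

    def test_matches_brute_force_oracle_on_random_datasets(self):
        rng = np.random.default_rng(13)
        for _ in range(25):
            ds = random_dataset(rng, n_max=200, n_items_max=10)
            m_min = float(rng.choice([0.05, 0.1, 0.2]))
            c_min = float(rng.choice([0.3, 0.5, 0.7]))
            rules = mine_class_rules(ds, 1, MiningParams(m_min=m_min, c_min=c_min, l_max=3))
            expected = brute_force_mine(ds, 1, m_min, c_min, 3)
            got = {r.lhs: (r.commonality, r.confidence) for r in rules}
            assert got.keys() == expected.keys()
            for lhs, (comm, conf) in expected.items():
                assert got[lhs][0] == pytest.approx(comm, abs=1e-12)
                assert got[lhs][1] == pytest.approx(conf, abs=1e-12)

    def test_equivalent_to_support_threshold_mining_on_s_all(self):
        # mining S_w at m_min yields the itemsets of the class-w rules found
        # by support-threshold mining on S_all at m_min*|S_w|/|S_all|
        from fractions import Fraction
        from itertools import combinations

        from oracles import naive_match_count

        rng = np.random.default_rng(17)
        for _ in range(10):
            ds = random_dataset(rng, n_max=120, n_items_max=8)
            n_w, n = len(ds.s_w(1)), len(ds)
            m_min = 0.15
            via_sw = {
                s for s, _ in mine_frequent_itemsets(ds.s_w(1), m_min, 3, ds.vocabulary_ids())
            }
            s_min_equiv = Fraction(m_min) * Fraction(n_w, n)
            vocab = ds.vocabulary_ids()
            via_sall = set()
            for k in range(1, 4):
                for combo in combinations(vocab, k):
                    lhs = frozenset(combo)
                    support_count = naive_match_count(lhs, ds.s_w(1))
                    if Fraction(support_count, n) >= s_min_equiv:
                        via_sall.add(lhs)
            assert via_sw == via_sall

    def test_mining_invariant_to_transaction_order(self, fixture_a_dataset):
        params = MiningParams(m_min=0.25, c_min=0.4, l_max=3)
        fwd = mine_class_rules(fixture_a_dataset, 1, params)
        rev = mine_class_rules(
            Dataset(tuple(reversed(fixture_a_dataset.transactions)), interesting_values=(1,)),
            1,
            params,
        )
        assert [(r.lhs, r.commonality, r.confidence) for r in fwd] == [
            (r.lhs, r.commonality, r.confidence) for r in rev
        ]

    def test_kb_pre_mining_restricts_lhs_to_allowed_items(self, fixture_a_dataset, abc_kb):
        from cbar.knowledge_base import KnowledgeBase

        kb = KnowledgeBase(frozenset({"A"}), {})
        rules = mine_class_rules(
            fixture_a_dataset, 1, MiningParams(m_min=0.25, c_min=0.4, l_max=2), kb=kb
        )
        assert all(r.lhs <= {"A"} for r in rules)

    def test_interventions_attached_when_kb_given(self, fixture_a_dataset, abc_kb):
        rules = mine_class_rules(
            fixture_a_dataset, 1, MiningParams(m_min=0.5, c_min=0.5, l_max=2), kb=abc_kb
        )
        by_lhs = {r.lhs: r for r in rules}
        assert by_lhs[frozenset({"A", "B"})].actionable
        assert {iv.intervention_id for iv in by_lhs[frozenset({"A", "B"})].interventions} == {
            "I1",
            "I2",
        }

    def test_legacy_support_threshold_mode(self, fixture_a_dataset):
        # s_min on S_all = 0.3 corresponds to commonality 0.3*10/4 = 0.75
        params = MiningParams(m_min=None, s_min=0.3, c_min=0.4, l_max=2)
        rules = mine_class_rules(fixture_a_dataset, 1, params)
        assert {tuple(sorted(r.lhs)) for r in rules} == {("A",), ("B",)}

    def test_jsonl_round_trip(self, fixture_a_dataset, tmp_path, abc_kb):
        rules = mine_class_rules(
            fixture_a_dataset, 1, MiningParams(m_min=0.5, c_min=0.5, l_max=2), kb=abc_kb
        )
        p = tmp_path / "rules.jsonl"
        rules_to_jsonl(rules, p)
        assert rules_from_jsonl(p) == rules


class TestSampling:
    def test_fraction_one_returns_identical_transactions(self, fixture_a_dataset):
        out = sample_dataset(fixture_a_dataset, 1.0, seed=3)
        assert out.transactions == fixture_a_dataset.transactions
        assert out.provenance == "sample"

    def test_same_seed_same_sample(self, fixture_a_dataset):
        a = sample_dataset(fixture_a_dataset, 0.4, seed=9)
        b = sample_dataset(fixture_a_dataset, 0.4, seed=9)
        assert a.transactions == b.transactions

    def test_ceil_sample_size(self, fixture_a_dataset):
        assert len(sample_dataset(fixture_a_dataset, 0.5, seed=1)) == 5
        assert len(sample_dataset(fixture_a_dataset, 0.01, seed=1)) == 1

    @pytest.mark.parametrize("fraction", [0.0, -0.1, 1.5])
    def test_bad_fraction_is_parameter_error(self, fixture_a_dataset, fraction):
        with pytest.raises(ParameterError):
            sample_dataset(fixture_a_dataset, fraction, seed=0)


class TestParams:
    def test_rule_requires_nonempty_lhs(self):
        with pytest.raises(MiningError):
            Rule(lhs=frozenset(), rhs=1, commonality=1, confidence=1, support=0.1)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"m_min": 0.0},
            {"m_min": 1.5},
            {"c_min": 0.0},
            {"l_max": 0},
            {"tau": -0.1},
            {"sample_fraction": 0.0},
            {"m_min": None},  # and no s_min
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            MiningParams(**kwargs)
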