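import math

import numpy as np
import pytest

from cbar.data_model import (
    DiscretizationSpec,
    Dataset,
    EncodingError,
    FeatureSchema,
    Item,
    SchemaError,
    Transaction,
    UnknownItemError,
    build_bitmap_index,
    derive_vocabulary,
    discretize_feature,
    encode_instance,
    match_count,
)
from oracles import naive_match_count


class TestDiscretize:
    def test_constant_values_yield_single_degenerate_bin(self):
        spec = discretize_feature([5, 5, 5, 5], n_bins=4)
        assert spec.boundaries == ()

    def test_equal_frequency_midpoint_boundary(self):
        spec = discretize_feature(list(range(1, 9)), n_bins=2, strategy="equal_frequency")
        assert spec.boundaries == (4.5,)

    def test_equal_width_boundaries(self):
        spec = discretize_feature([0, 10], n_bins=2, strategy="equal_width")
        assert spec.boundaries == (5.0,)

    @pytest.mark.parametrize("strategy", ["equal_frequency", "equal_width"])
    def test_every_value_falls_in_exactly_one_bin(self, strategy):
        rng = np.random.default_rng(42)
        for _ in range(20):
            values = rng.normal(size=rng.integers(5, 60)).tolist()
            n_bins = int(rng.integers(1, 6))
            spec = discretize_feature(values, n_bins, strategy)
            assert len(spec.boundaries) <= n_bins - 1 or n_bins == 1
            assert all(b2 > b1 for b1, b2 in zip(spec.boundaries, spec.boundaries[1:]))
            for v in values:
                assert 0 <= spec.bin_of(v) <= len(spec.boundaries)

    def test_deterministic(self):
        vals = [3.1, 0.2, 9.9, 4.4, 4.4, 7.0]
        assert discretize_feature(vals, 3) == discretize_feature(vals, 3)

    def test_all_missing_is_schema_error(self):
        with pytest.raises(SchemaError):
            discretize_feature([float("nan"), None], 3)


class TestItems:
    def test_interval_rendering_matches_printed_ranges(self):
        it = Item("los:in:1.75:2.95", "los", "interval", low=1.75, high=2.95)
        assert ">1.75 and ≤2.95" in it.render()

    def test_interval_requires_low_lt_high(self):
        with pytest.raises(SchemaError):
            Item("bad", "f", "interval", low=2.0, high=2.0)

    def test_rendering_injective_over_derived_vocabulary(self):
        schema = [
            FeatureSchema("x", "continuous", discretization=DiscretizationSpec((1.0, 2.0))),
            FeatureSchema("y", "categorical", categories=("a", "b")),
        ]
        items = derive_vocabulary(schema)
        renderings = [it.render() for it in items]
        assert len(set(renderings)) == len(renderings)
        # bins partition the line: every value matched by exactly one x-item
        x_items = [it for it in items if it.feature_id == "x"]
        for v in (-3.0, 1.0, 1.5, 2.0, 7.0):
            assert sum(it.matches(v) for it in x_items) == 1


class TestEncode:
    SCHEMA = [
        FeatureSchema("ed_visits", "continuous", discretization=DiscretizationSpec(())),
        FeatureSchema("color", "categorical", categories=("red", "blue")),
    ]
    VOCAB = [
        Item("ed12", "ed_visits", "at_least", value=12),
        Item("red", "color", "equals", value="red"),
    ]

    def test_threshold_item_fires(self):
        t = encode_instance({"ed_visits": 13, "color": "blue"}, self.SCHEMA, self.VOCAB)
        assert t.items == {"ed12"}

    def test_no_predicate_satisfied_gives_empty_set(self):
        t = encode_instance({"ed_visits": 2, "color": "blue"}, self.SCHEMA, self.VOCAB)
        assert t.items == frozenset()

    def test_missing_numeric_satisfies_no_numeric_item(self):
        t = encode_instance({"ed_visits": float("nan"), "color": "red"}, self.SCHEMA, self.VOCAB)
        assert t.items == {"red"}
        t = encode_instance({"ed_visits": None, "color": "red"}, self.SCHEMA, self.VOCAB)
        assert t.items == {"red"}

    def test_type_mismatch_is_encoding_error(self):
        with pytest.raises(EncodingError):
            encode_instance({"ed_visits": "many", "color": "red"}, self.SCHEMA, self.VOCAB)

    def test_unknown_feature_is_schema_error(self):
        vocab = self.VOCAB + [Item("zz", "unknown_feature", "equals", value=1)]
        with pytest.raises(SchemaError):
            encode_instance({"ed_visits": 1, "color": "red"}, self.SCHEMA, vocab)

    def test_fixture_a_row2_reencodes_from_raw_form(self, fixture_a_dataset):
        schema = [
            FeatureSchema(f, "categorical", categories=(0, 1)) for f in ("A", "B", "C")
        ]
        vocab = [Item(f, f, "equals", value=1) for f in ("A", "B", "C")]
        t = encode_instance({"A": 1, "B": 1, "C": 1}, schema, vocab, instance_id=2, outcome=1)
        assert t.items == fixture_a_dataset.transactions[1].items == {"A", "B", "C"}


class TestBitmapIndex:
    def test_fixture_popcounts(self, fixture_a_index):
        assert fixture_a_index.popcount("A") == 6
        assert int(fixture_a_index.itemset_mask({"A", "B"}).sum()) == 3

    def test_absent_item_gives_zero_vector(self, fixture_a_dataset):
        idx = build_bitmap_index(fixture_a_dataset, vocabulary=["A", "B", "C", "Z"])
        assert idx.popcount("Z") == 0

    def test_rebuild_is_bit_identical(self, fixture_a_dataset):
        i1 = build_bitmap_index(fixture_a_dataset)
        i2 = build_bitmap_index(fixture_a_dataset)
        for iid in i1.item_ids:
            assert np.array_equal(i1.vector(iid), i2.vector(iid))

    def test_unindexed_transaction_item_is_error(self, fixture_a_dataset):
        with pytest.raises(UnknownItemError):
            build_bitmap_index(fixture_a_dataset, vocabulary=["A", "B"])

    def test_unknown_item_lookup_is_error(self, fixture_a_index):
        with pytest.raises(UnknownItemError):
            match_count({"missing"}, fixture_a_index)


class TestMatchCount:
    def test_empty_itemset_matches_all(self, fixture_a_index):
        assert match_count(set(), fixture_a_index, "all") == 10

    def test_fixture_scoped_counts(self, fixture_a_index):
        assert match_count({"A"}, fixture_a_index, "w") == 3
        assert match_count({"C"}, fixture_a_index, "not_w") == 3

    def test_partition_identity_and_antimonotonicity(self, fixture_a_index):
        itemsets = [set(), {"A"}, {"B"}, {"C"}, {"A", "B"}, {"A", "C"}, {"A", "B", "C"}]
        for s in itemsets:
            assert (
                match_count(s, fixture_a_index, "w")
                + match_count(s, fixture_a_index, "not_w")
                == match_count(s, fixture_a_index, "all")
            )
        for small, big in [({"A"}, {"A", "B"}), ({"B"}, {"A", "B"}), ({"A", "B"}, {"A", "B", "C"})]:
            assert match_count(big, fixture_a_index) <= match_count(small, fixture_a_index)

    def test_bitmap_counts_equal_naive_subset_test_on_random_data(self):
        from conftest import random_dataset

        rng = np.random.default_rng(2024)
        checked = 0
        while checked < 1000:
            ds = random_dataset(rng, n_max=80, n_items_max=8)
            idx = build_bitmap_index(ds, vocabulary=[f"i{j}" for j in range(8)])
            for _ in range(25):
                size = int(rng.integers(0, 4))
                itemset = set(rng.choice([f"i{j}" for j in range(8)], size=size, replace=False))
                assert match_count(itemset, idx) == naive_match_count(itemset, ds.transactions)
                checked += 1

    def test_counts_invariant_to_vocabulary_declaration_order(self, fixture_a_dataset):
        fwd = build_bitmap_index(fixture_a_dataset, vocabulary=["A", "B", "C"])
        rev = build_bitmap_index(fixture_a_dataset, vocabulary=["C", "B", "A"])
        for s in [{"A"}, {"B", "C"}, {"A", "B", "C"}]:
            assert match_count(s, fwd) == match_count(s, rev)
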