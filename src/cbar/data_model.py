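"""Item vocabulary, transaction encoding, and the bitmap co-occurrence index.

A *transaction* is a data instance rendered as the set of vocabulary items
(feature-value predicates) it satisfies, together with its outcome class.
Continuous features are discretized into left-open/right-closed intervals
before items are formed, so every printed range reads like ">a and ≤b".

The :class:`BitmapIndex` keeps one boolean vector per item over a fixed row
ordering; co-occurrence counts reduce to bitwise AND plus popcount, which is
what makes confidence verification over large cohorts cheap.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SchemaError",
    "EncodingError",
    "UnknownItemError",
    "DiscretizationSpec",
    "Item",
    "FeatureSchema",
    "Transaction",
    "Dataset",
    "BitmapIndex",
    "discretize_feature",
    "encode_instance",
    "build_bitmap_index",
    "match_count",
    "derive_vocabulary",
    "load_sidecar",
    "load_table",
    "items_to_json",
    "items_from_json",
]


class SchemaError(ValueError):
    """Schema/vocabulary inconsistency (unknown feature, bad spec, ...)."""


class EncodingError(ValueError):
    """A raw value is incompatible with its declared feature kind."""


class UnknownItemError(KeyError):
    """An item_id is not present in the bitmap index / vocabulary."""


@dataclass(frozen=True)
class DiscretizationSpec:
    """Strictly increasing cut points defining left-open/right-closed bins.

    k boundaries partition the real line into k+1 intervals
    (-inf, b0], (b0, b1], ..., (b_{k-1}, +inf).
    """

    boundaries: tuple[float, ...]

    def __post_init__(self) -> None:
        bs = tuple(float(b) for b in self.boundaries)
        object.__setattr__(self, "boundaries", bs)
        if any(b2 <= b1 for b1, b2 in zip(bs, bs[1:])):
            raise SchemaError(f"boundaries must be strictly increasing: {bs}")

    def bin_of(self, value: float) -> int:
        """Index of the interval containing ``value`` (0..len(boundaries))."""
        # left-open/right-closed: value <= b falls in the bin ending at b
        return int(np.searchsorted(np.asarray(self.boundaries), value, side="left"))


@dataclass(frozen=True)
class Item:
    """A feature-value predicate: equality, one-sided threshold, or interval.

    Interval items are left-open/right-closed; open-ended intervals use
    -inf / +inf bounds, so "> b" is interval(low=b, high=inf).
    """

    item_id: str
    feature_id: str
    predicate_kind: str  # equals | at_least | at_most | interval
    value: object = None
    low: float | None = None
    high: float | None = None

    _KINDS = ("equals", "at_least", "at_most", "interval")

    def __post_init__(self) -> None:
        if self.predicate_kind not in self._KINDS:
            raise SchemaError(f"unknown predicate_kind {self.predicate_kind!r}")
        if self.predicate_kind == "interval":
            if self.low is None or self.high is None or not self.low < self.high:
                raise SchemaError(
                    f"interval item {self.item_id!r} requires low < high, "
                    f"got ({self.low}, {self.high})"
                )
        elif self.predicate_kind in ("at_least", "at_most"):
            if self.value is None or not _is_number(self.value):
                raise SchemaError(
                    f"{self.predicate_kind} item {self.item_id!r} needs a numeric value"
                )

    def matches(self, raw: object) -> bool:
        """Whether a raw feature value satisfies this predicate.

        Missing numeric values (None/NaN) never satisfy a numeric item.
        """
        if self.predicate_kind == "equals":
            return raw == self.value
        if raw is None or not _is_number(raw) or math.isnan(float(raw)):
            return False
        v = float(raw)
        if self.predicate_kind == "at_least":
            return v >= float(self.value)
        if self.predicate_kind == "at_most":
            return v <= float(self.value)
        return self.low < v <= self.high

    def render(self) -> str:
        """Canonical human-readable text; injective over distinct items."""
        f = self.feature_id
        if self.predicate_kind == "equals":
            return f"{f} = {self.value}"
        if self.predicate_kind == "at_least":
            return f"{f} ≥ {_fmt(self.value)}"
        if self.predicate_kind == "at_most":
            return f"{f} ≤ {_fmt(self.value)}"
        if math.isinf(self.high):
            return f"{f} is >{_fmt(self.low)}"
        if math.isinf(self.low):
            return f"{f} is ≤{_fmt(self.high)}"
        return f"{f} is >{_fmt(self.low)} and ≤{_fmt(self.high)}"

    def to_dict(self) -> dict:
        d = {
            "item_id": self.item_id,
            "feature_id": self.feature_id,
            "predicate": self.predicate_kind,
            "rendering": self.render(),
        }
        if self.predicate_kind == "interval":
            d["low"], d["high"] = self.low, self.high
        else:
            d["value"] = self.value
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "Item":
        return cls(
            item_id=d["item_id"],
            feature_id=d["feature_id"],
            predicate_kind=d.get("predicate", d.get("predicate_kind")),
            value=d.get("value"),
            low=d.get("low"),
            high=d.get("high"),
        )


def _is_number(x: object) -> bool:
    return isinstance(x, (int, float, np.integer, np.floating)) and not isinstance(x, bool)


def _fmt(x: object) -> str:
    return f"{float(x):g}"


@dataclass(frozen=True)
class FeatureSchema:
    """Declaration of one input feature."""

    feature_id: str
    kind: str  # continuous | categorical
    unit: str = ""
    discretization: DiscretizationSpec | None = None
    categories: tuple | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "categorical"):
            raise SchemaError(f"feature kind must be continuous/categorical: {self.kind!r}")
        if self.kind == "categorical" and self.categories is None:
            raise SchemaError(f"categorical feature {self.feature_id!r} needs categories")


@dataclass(frozen=True)
class Transaction:
    instance_id: object
    items: frozenset
    outcome: object

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", frozenset(self.items))


@dataclass(frozen=True)
class Dataset:
    """Ordered transactions plus the outcome values flagged as interesting.

    Row order is fixed at load time; all sequential scans (including the
    early-termination confidence check) follow it.
    """

    transactions: tuple[Transaction, ...]
    interesting_values: tuple = ()
    provenance: str = "full"

    def __post_init__(self) -> None:
        object.__setattr__(self, "transactions", tuple(self.transactions))
        object.__setattr__(self, "interesting_values", tuple(self.interesting_values))

    def __len__(self) -> int:
        return len(self.transactions)

    def __iter__(self):
        return iter(self.transactions)

    def s_w(self, w: object) -> list[Transaction]:
        """Transactions linking to the interesting value w."""
        return [t for t in self.transactions if t.outcome == w]

    def s_not_w(self, w: object) -> list[Transaction]:
        return [t for t in self.transactions if t.outcome != w]

    def vocabulary_ids(self) -> list[str]:
        seen: set = set()
        for t in self.transactions:
            seen |= t.items
        return sorted(seen)


class BitmapIndex:
    """One boolean column per item over the dataset's fixed row order.

    The popcount of an item's vector is the number of transactions containing
    it; AND-ing an itemset's vectors marks exactly the co-occurring rows.
    """

    def __init__(self, dataset: Dataset, vocabulary: Sequence | None = None):
        self.n = len(dataset)
        if vocabulary is None:
            item_ids = dataset.vocabulary_ids()
        else:
            item_ids = [it.item_id if isinstance(it, Item) else it for it in vocabulary]
        known = set(item_ids)
        vectors: dict[str, np.ndarray] = {
            iid: np.zeros(self.n, dtype=bool) for iid in item_ids
        }
        for row, t in enumerate(dataset):
            for iid in t.items:
                if iid not in known:
                    raise UnknownItemError(
                        f"transaction {t.instance_id!r} references item {iid!r} "
                        "absent from the vocabulary"
                    )
                vectors[iid][row] = True
        for v in vectors.values():
            v.flags.writeable = False
        self._vectors = vectors
        self._outcomes = np.array([t.outcome for t in dataset], dtype=object)
        self.interesting_values = dataset.interesting_values

    @property
    def item_ids(self) -> list[str]:
        return list(self._vectors)

    def vector(self, item_id: str) -> np.ndarray:
        try:
            return self._vectors[item_id]
        except KeyError:
            raise UnknownItemError(f"item {item_id!r} not indexed") from None

    def popcount(self, item_id: str) -> int:
        return int(self.vector(item_id).sum())

    def itemset_mask(self, itemset: Iterable[str]) -> np.ndarray:
        """AND over the itemset's vectors; all-true for the empty itemset."""
        mask = np.ones(self.n, dtype=bool)
        for iid in itemset:
            mask &= self.vector(iid)
        return mask

    def class_mask(self, w: object) -> np.ndarray:
        return self._outcomes == w

    def outcome_of_row(self, row: int) -> object:
        return self._outcomes[row]


def build_bitmap_index(dataset: Dataset, vocabulary: Sequence | None = None) -> BitmapIndex:
    """Build a :class:`BitmapIndex`; bit-identical when rebuilt on same data."""
    return BitmapIndex(dataset, vocabulary)


def match_count(
    itemset: Iterable[str],
    index: BitmapIndex,
    scope: str = "all",
    w: object = None,
) -> int:
    """Number of transactions in a restriction containing every item.

    ``scope`` is one of ``"all"``, ``"w"`` (outcome == w) or ``"not_w"``.
    The empty itemset matches every transaction in the restriction.
    """
    mask = index.itemset_mask(itemset)
    if scope == "all":
        return int(mask.sum())
    if w is None:
        if len(index.interesting_values) != 1:
            raise ValueError("w is required when the dataset has no single interesting value")
        w = index.interesting_values[0]
    cls = index.class_mask(w)
    if scope == "w":
        return int((mask & cls).sum())
    if scope == "not_w":
        return int((mask & ~cls).sum())
    raise ValueError(f"scope must be all/w/not_w, got {scope!r}")


def discretize_feature(
    values: Sequence[float],
    n_bins: int,
    strategy: str = "equal_frequency",
) -> DiscretizationSpec:
    """Automatic discretization of a continuous feature into ≤ n_bins bins.

    equal_frequency places boundaries at midpoints between the order
    statistics at the quantile cut positions; equal_width splits the observed
    range evenly. Duplicate/degenerate cuts are merged, so constant input
    yields zero boundaries (a single bin). Deterministic for a given input.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    arr = np.asarray(
        [v for v in values if v is not None and _is_number(v) and not math.isnan(float(v))],
        dtype=float,
    )
    if arr.size == 0:
        raise SchemaError("cannot discretize: no numeric values")
    if strategy not in ("equal_frequency", "equal_width"):
        raise ValueError(f"unknown strategy {strategy!r}")
    if n_bins == 1:
        return DiscretizationSpec(())
    if strategy == "equal_width":
        lo, hi = float(arr.min()), float(arr.max())
        if lo == hi:
            return DiscretizationSpec(())
        cuts = np.linspace(lo, hi, n_bins + 1)[1:-1]
    else:
        s = np.sort(arr)
        n = s.size
        cuts = []
        for i in range(1, n_bins):
            pos = int(round(i * n / n_bins))
            pos = min(max(pos, 1), n - 1)
            cuts.append((s[pos - 1] + s[pos]) / 2.0)
        cuts = np.asarray(cuts)
    out: list[float] = []
    for c in cuts:
        if not out or c > out[-1]:
            out.append(float(c))
    # a boundary at/below min or at/above max would create an empty bin
    out = [c for c in out if arr.min() <= c < arr.max()]
    return DiscretizationSpec(tuple(out))


def derive_vocabulary(schema: Sequence[FeatureSchema]) -> list[Item]:
    """Default item vocabulary: one interval item per bin, one equality item
    per declared category. Continuous features must carry a DiscretizationSpec."""
    items: list[Item] = []
    for f in schema:
        if f.kind == "continuous":
            if f.discretization is None:
                raise SchemaError(
                    f"continuous feature {f.feature_id!r} has no discretization"
                )
            bs = f.discretization.boundaries
            if not bs:
                continue  # degenerate single bin: no interval items
            items.append(
                Item(f"{f.feature_id}:le:{_fmt(bs[0])}", f.feature_id, "at_most", value=bs[0])
            )
            for lo, hi in zip(bs, bs[1:]):
                items.append(
                    Item(
                        f"{f.feature_id}:in:{_fmt(lo)}:{_fmt(hi)}",
                        f.feature_id,
                        "interval",
                        low=lo,
                        high=hi,
                    )
                )
            items.append(
                Item(
                    f"{f.feature_id}:gt:{_fmt(bs[-1])}",
                    f.feature_id,
                    "interval",
                    low=bs[-1],
                    high=math.inf,
                )
            )
        else:
            for cat in f.categories:
                items.append(Item(f"{f.feature_id}:eq:{cat}", f.feature_id, "equals", value=cat))
    ids = [it.item_id for it in items]
    if len(set(ids)) != len(ids):
        raise SchemaError("derived vocabulary has duplicate item_ids")
    return items


def encode_instance(
    record: Mapping,
    schema: Sequence[FeatureSchema],
    vocabulary: Sequence[Item],
    instance_id: object = None,
    outcome: object = None,
) -> Transaction:
    """Render a raw record as the set of vocabulary items it satisfies.

    Missing numeric values satisfy no numeric item; a categorical missing is
    matched only by an equality item explicitly declaring that category.
    """
    by_feature: dict[str, FeatureSchema] = {f.feature_id: f for f in schema}
    for it in vocabulary:
        if it.feature_id not in by_feature:
            raise SchemaError(f"item {it.item_id!r} references unknown feature {it.feature_id!r}")
    satisfied = set()
    for it in vocabulary:
        if it.feature_id not in record:
            raise SchemaError(f"record missing feature {it.feature_id!r}")
        raw = record[it.feature_id]
        feat = by_feature[it.feature_id]
        if (
            feat.kind == "continuous"
            and raw is not None
            and not _is_number(raw)
        ):
            raise EncodingError(
                f"feature {it.feature_id!r} is continuous but got {raw!r}"
            )
        if it.matches(raw):
            satisfied.add(it.item_id)
    return Transaction(instance_id=instance_id, items=frozenset(satisfied), outcome=outcome)


# ---------------------------------------------------------------------------
# Delimited-text I/O: data CSV/TSV + YAML/JSON sidecar (schema & vocabulary)

def items_to_json(items: Sequence[Item], path: str | Path) -> None:
    Path(path).write_text(json.dumps([it.to_dict() for it in items], indent=1))


def items_from_json(path: str | Path) -> list[Item]:
    return [Item.from_dict(d) for d in json.loads(Path(path).read_text())]


def load_sidecar(path: str | Path):
    """Read schema/vocabulary sidecar (YAML or JSON).

    Returns (schema, vocabulary, outcome_column, interesting_values).
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    schema = []
    for f in raw.get("features", []):
        disc = None
        if "boundaries" in f:
            disc = DiscretizationSpec(tuple(f["boundaries"]))
        cats = tuple(f["categories"]) if "categories" in f else None
        schema.append(
            FeatureSchema(
                feature_id=f["feature_id"],
                kind=f["kind"],
                unit=f.get("unit", ""),
                discretization=disc,
                categories=cats,
            )
        )
    if "vocabulary" in raw:
        vocabulary = [Item.from_dict(d) for d in raw["vocabulary"]]
    else:
        vocabulary = derive_vocabulary(schema)
    outcome_col = raw.get("outcome", "outcome")
    interesting = tuple(raw.get("interesting_values", ()))
    return schema, vocabulary, outcome_col, interesting


def load_table(data_path: str | Path, sidecar_path: str | Path) -> Dataset:
    """Load a delimited table + sidecar into a Dataset (row order = file order)."""
    data_path = Path(data_path)
    schema, vocabulary, outcome_col, interesting = load_sidecar(sidecar_path)
    sep = "\t" if data_path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(data_path, sep=sep)
    if outcome_col not in df.columns:
        raise SchemaError(f"outcome column {outcome_col!r} not in {data_path.name}")
    id_col = "instance_id" if "instance_id" in df.columns else None
    transactions = []
    for pos, (_, row) in enumerate(df.iterrows()):
        rec = row.to_dict()
        outcome = rec.pop(outcome_col)
        iid = rec.pop(id_col) if id_col else pos
        transactions.append(
            encode_instance(rec, schema, vocabulary, instance_id=iid, outcome=outcome)
        )
    return Dataset(tuple(transactions), interesting_values=interesting)
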