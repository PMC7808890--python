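"""Two-step class-based association rule mining for imbalanced outcomes.

For each interesting outcome value w, rules "q1 AND ... AND qn → w" are mined
in two steps:

1. Level-wise (Apriori-style) frequent itemset search over S_w, the instances
   linking to w, under a minimum *commonality* threshold m_min. Commonality is
   value-specific support: of the instances linking to w, the fraction whose
   transactions contain the whole left-hand side. Because commonality is
   anti-monotone, candidate (k)-itemsets are generated only from frequent
   (k-1)-itemsets. Mining on S_w at threshold m_min is equivalent to mining
   all instances at support threshold m_min*|S_w|/|S_all| and keeping the
   class-w rules, but far cheaper when w is rare.

2. Confidence verification on all instances. For a candidate left-hand side,
   l_w instances in S_w match; the scan over S_¬w stops as soon as the running
   match count exceeds T_l = l_w*(1-c_min)/c_min, because at that point the
   confidence l_w/(l_w+l_¬w) is provably below c_min.

Only commonality and confidence gate retention; support is reported and obeys
support = commonality * |S_w|/|S_all| exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .data_model import BitmapIndex, Dataset, Item, Transaction, build_bitmap_index
from .knowledge_base import KnowledgeBase, attach_interventions, filter_transaction

__all__ = [
    "MiningError",
    "ParameterError",
    "MiningParams",
    "Rule",
    "ConfidenceCounter",
    "Accept",
    "Reject",
    "mine_frequent_itemsets",
    "confidence_with_early_stop",
    "mine_class_rules",
    "sample_dataset",
    "rules_to_jsonl",
    "rules_from_jsonl",
]


class MiningError(ValueError):
    pass


class ParameterError(ValueError):
    pass


@dataclass(frozen=True)
class MiningParams:
    """Thresholds controlling rule mining.

    m_min: minimum commonality in (0, 1]. May be None only when the legacy
        balanced-data support threshold s_min is given instead.
    c_min: minimum confidence in (0, 1].
    l_max: maximum number of left-hand-side items (long rules are hard to
        read; 4-5 is typical, the harder the outcome the larger).
    tau: confidence-difference threshold used downstream by generality
        pruning (kept here so one object configures a whole run).
    s_min: optional legacy minimum support on all instances; converted to an
        effective commonality threshold s_min*|S_all|/|S_w| when m_min is None.
    sample_fraction: fraction of instances to mine on (uniform, seeded).
    """

    m_min: float | None = 0.002
    c_min: float = 0.5
    l_max: int = 5
    tau: float = 0.15
    s_min: float | None = None
    sample_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m_min is None and self.s_min is None:
            raise ParameterError("one of m_min / s_min is required")
        if self.m_min is not None and not 0 < self.m_min <= 1:
            raise ParameterError(f"m_min must be in (0,1], got {self.m_min}")
        if not 0 < self.c_min <= 1:
            raise ParameterError(f"c_min must be in (0,1], got {self.c_min}")
        if self.l_max < 1:
            raise ParameterError(f"l_max must be >= 1, got {self.l_max}")
        if self.tau < 0:
            raise ParameterError(f"tau must be >= 0, got {self.tau}")
        if self.s_min is not None and not 0 < self.s_min <= 1:
            raise ParameterError(f"s_min must be in (0,1], got {self.s_min}")
        if not 0 < self.sample_fraction <= 1:
            raise ParameterError(f"sample_fraction must be in (0,1], got {self.sample_fraction}")


@dataclass(frozen=True)
class Rule:
    """A class-based association rule lhs → rhs with its exact statistics."""

    lhs: frozenset
    rhs: object
    commonality: float
    confidence: float
    support: float
    interventions: tuple = ()
    actionable: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "lhs", frozenset(self.lhs))
        if not self.lhs:
            raise MiningError("rules must have at least one left-hand-side item")

    def sort_key(self):
        return (len(self.lhs), tuple(sorted(self.lhs)))

    def render(self, vocabulary: dict[str, Item] | None = None) -> str:
        parts = []
        for iid in sorted(self.lhs):
            parts.append(vocabulary[iid].render() if vocabulary and iid in vocabulary else str(iid))
        return (
            f"{' AND '.join(parts)} → {self.rhs} "
            f"(confidence {self.confidence:.3f}, commonality {self.commonality:.3f})"
        )

    def to_dict(self) -> dict:
        return {
            "lhs": sorted(self.lhs),
            "rhs": self.rhs,
            "commonality": self.commonality,
            "confidence": self.confidence,
            "support": self.support,
            "actionable": self.actionable,
            "interventions": [
                {"intervention_id": iv.intervention_id, "item_id": iv.item_id, "text": iv.text}
                for iv in self.interventions
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Rule":
        from .knowledge_base import Intervention

        return cls(
            lhs=frozenset(d["lhs"]),
            rhs=d["rhs"],
            commonality=d["commonality"],
            confidence=d["confidence"],
            support=d["support"],
            interventions=tuple(
                Intervention(x["intervention_id"], x["text"], x["item_id"])
                for x in d.get("interventions", ())
            ),
            actionable=d.get("actionable", False),
        )


@dataclass
class ConfidenceCounter:
    """Running counters for the confidence check of one candidate rule."""

    l_w: int
    l_not_w: int = 0

    def t_l(self, c_min: float) -> float:
        """Early-stop bound: l_w * (1 - c_min) / c_min."""
        return self.l_w * (1 - c_min) / c_min

    def confidence(self) -> float:
        total = self.l_w + self.l_not_w
        return self.l_w / total if total else 0.0


@dataclass(frozen=True)
class Accept:
    confidence: float
    l_w: int
    l_not_w: int


@dataclass(frozen=True)
class Reject:
    rows_scanned: int  # S_¬w rows examined before the bound was exceeded


def _item_ids(vocabulary: Sequence) -> list[str]:
    return [it.item_id if isinstance(it, Item) else it for it in vocabulary]


def mine_frequent_itemsets(
    s_w: Sequence[Transaction],
    m_min: float,
    l_max: int,
    vocabulary: Sequence,
) -> list[tuple[frozenset, float]]:
    """All itemsets of size 1..l_max with commonality >= m_min on S_w.

    Level-wise generation: (k)-candidates are joins of (k-1)-frequent sets
    sharing a (k-2)-prefix, pruned when any (k-1)-subset is infrequent
    (commonality is anti-monotone). Returns (itemset, exact commonality).
    """
    n = len(s_w)
    if n == 0:
        raise MiningError("no instances of interesting value")
    vocab_ids = sorted(set(_item_ids(vocabulary)))
    columns = {
        iid: np.fromiter((iid in t.items for t in s_w), dtype=bool, count=n)
        for iid in vocab_ids
    }
    # integer threshold: count/n >= m_min  <=>  count >= ceil(m_min * n)
    frac = Fraction(m_min)
    min_count = -((-frac.numerator * n) // frac.denominator)  # ceil
    min_count = max(min_count, 1)

    results: list[tuple[frozenset, float]] = []
    level: dict[tuple, np.ndarray] = {}
    for iid in vocab_ids:
        c = int(columns[iid].sum())
        if c >= min_count:
            level[(iid,)] = columns[iid]
            results.append((frozenset((iid,)), c / n))
    k = 1
    while k < l_max and level:
        keys = sorted(level)
        prev = set(keys)
        nxt: dict[tuple, np.ndarray] = {}
        for i, a in enumerate(keys):
            for b in keys[i + 1:]:
                if a[:-1] != b[:-1]:
                    break  # sorted: prefixes diverge from here on
                cand = a + (b[-1],)
                # subset pruning: every k-subset must be frequent
                if any(
                    cand[:j] + cand[j + 1:] not in prev for j in range(len(cand) - 2)
                ):
                    continue
                vec = level[a] & columns[b[-1]]
                c = int(vec.sum())
                if c >= min_count:
                    nxt[cand] = vec
                    results.append((frozenset(cand), c / n))
        level = nxt
        k += 1
    return results


def _stop_count(l_w: int, c_min: float) -> int:
    """Smallest integer S_¬w match count that proves confidence < c_min.

    Exceeding T_l = l_w*(1-c_min)/c_min means rejection; the comparison is
    done in exact rational arithmetic on the float c_min so the early-stop
    decision is bit-identical to a full-count confidence test.
    """
    frac = Fraction(c_min)
    t_floor = (l_w * (frac.denominator - frac.numerator)) // frac.numerator
    return int(t_floor) + 1


def confidence_with_early_stop(
    itemset: Iterable[str],
    w: object,
    index: BitmapIndex,
    c_min: float,
    chunk: int = 4096,
) -> Accept | Reject:
    """Verify a candidate rule's confidence on all instances, stopping early.

    Scans S_¬w in the dataset's fixed row order in chunks; rejects as soon as
    the running match count exceeds T_l, reporting how many S_¬w rows were
    examined. An Accept carries the exact confidence and both counts.
    """
    itemset = frozenset(itemset)
    if not itemset:
        raise MiningError("confidence check requires a non-empty itemset")
    mask = index.itemset_mask(itemset)
    cls = index.class_mask(w)
    l_w = int((mask & cls).sum())
    if l_w == 0:
        return Reject(rows_scanned=0)
    stop_at = _stop_count(l_w, c_min)
    neg_matches = mask[~cls]  # S_¬w rows in load order
    count = 0
    for start in range(0, neg_matches.size, chunk):
        seg = neg_matches[start : start + chunk]
        csum = count + np.cumsum(seg)
        pos = int(np.searchsorted(csum, stop_at, side="left"))
        if pos < seg.size:
            return Reject(rows_scanned=start + pos + 1)
        count = int(csum[-1]) if seg.size else count
    return Accept(confidence=l_w / (l_w + count), l_w=l_w, l_not_w=count)


def sample_dataset(dataset: Dataset, fraction: float, seed: int) -> Dataset:
    """Uniform sample without replacement of ceil(fraction*N) transactions.

    Row order of the sample follows the original load order; the same seed
    reproduces the same sample.
    """
    if not 0 < fraction <= 1:
        raise ParameterError(f"fraction must be in (0,1], got {fraction}")
    n = len(dataset)
    k = math.ceil(fraction * n)
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(n, size=k, replace=False))
    return Dataset(
        tuple(dataset.transactions[i] for i in idx),
        interesting_values=dataset.interesting_values,
        provenance="sample",
    )


def mine_class_rules(
    dataset: Dataset,
    w: object,
    params: MiningParams,
    kb: KnowledgeBase | None = None,
    vocabulary: Sequence | None = None,
    kb_application: str = "pre_mining",
) -> list[Rule]:
    """Mine every rule lhs → w meeting the commonality and confidence gates.

    With a knowledge base and kb_application="pre_mining", disallowed items
    are removed from transactions before mining (the efficient default);
    "post_mining" instead drops finished rules whose lhs strays outside the
    allowed set. Interventions are attached either way. The result is
    canonically ordered by (lhs size, sorted lhs).
    """
    if kb_application not in ("pre_mining", "post_mining"):
        raise ParameterError(f"kb_application must be pre/post_mining: {kb_application!r}")
    if params.sample_fraction < 1:
        dataset = sample_dataset(dataset, params.sample_fraction, params.seed)
    if kb is not None and kb_application == "pre_mining":
        dataset = Dataset(
            tuple(filter_transaction(t, kb) for t in dataset.transactions),
            interesting_values=dataset.interesting_values,
            provenance=dataset.provenance,
        )
    if not dataset.s_w(w):
        raise MiningError("no instances of interesting value")
    if vocabulary is None:
        vocab_ids = dataset.vocabulary_ids()
    else:
        vocab_ids = sorted(set(_item_ids(vocabulary)))
        if kb is not None and kb_application == "pre_mining":
            vocab_ids = [i for i in vocab_ids if i in kb.allowed_items]
        vocab_set = set(vocab_ids)
        dataset = Dataset(
            tuple(
                Transaction(t.instance_id, t.items & vocab_set, t.outcome)
                for t in dataset.transactions
            ),
            interesting_values=dataset.interesting_values,
            provenance=dataset.provenance,
        )
    s_w = dataset.s_w(w)
    m_min = params.m_min
    if m_min is None:
        # legacy balanced-data mode: support threshold on S_all
        m_min = min(1.0, params.s_min * len(dataset) / len(s_w))
    index = build_bitmap_index(dataset, vocabulary=vocab_ids)
    frequent = mine_frequent_itemsets(s_w, m_min, params.l_max, vocab_ids)
    n_all = len(dataset)
    rules: list[Rule] = []
    for itemset, commonality in frequent:
        outcome = confidence_with_early_stop(itemset, w, index, params.c_min)
        if isinstance(outcome, Reject):
            continue
        rule = Rule(
            lhs=itemset,
            rhs=w,
            commonality=commonality,
            confidence=outcome.confidence,
            support=outcome.l_w / n_all,
        )
        if kb is not None:
            if kb_application == "post_mining" and not rule.lhs <= kb.allowed_items:
                continue
            rule = attach_interventions(rule, kb)
        rules.append(rule)
    rules.sort(key=Rule.sort_key)
    return rules


def rules_to_jsonl(rules: Sequence[Rule], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in rules:
            fh.write(json.dumps(r.to_dict()) + "\n")


def rules_from_jsonl(path: str | Path) -> list[Rule]:
    rules = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                rules.append(Rule.from_dict(json.loads(line)))
    return rules
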