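"""Synthetic imbalanced cohorts with planted conjunctive rules.

Emulates the structure of a patient-year cohort where a small fraction of
instances link to the poor outcome (default base positive rate 4%), so the
whole pipeline is testable without clinical data. Each planted rule is a
conjunction of items carried jointly by a fraction of instances; carriers of
the highest-confidence firing rule take the poor outcome with that rule's
target confidence, everyone else at the base rate. Ground truth (the planted
parameters) is returned alongside the data.

The module also pins FIXTURE-A, a 10-transaction dataset over items A/B/C
used throughout the documentation and tests as a worked example.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import yaml

from .data_model import Dataset, Transaction

__all__ = [
    "PlantedRule",
    "CohortSpec",
    "RuleStats",
    "generate_cohort",
    "empirical_rule_stats",
    "fixture_a",
    "default_planted_rules",
    "demo_planted_rules",
    "write_cohort",
]

POSITIVE = 1
NEGATIVE = 0


@dataclass(frozen=True)
class PlantedRule:
    lhs: tuple[str, ...]
    target_confidence: float
    carrier_fraction: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "lhs", tuple(self.lhs))
        if not self.lhs:
            raise ValueError("planted rule lhs must be non-empty")
        if not 0 < self.target_confidence <= 1:
            raise ValueError(f"target_confidence in (0,1], got {self.target_confidence}")
        if not 0 < self.carrier_fraction <= 1:
            raise ValueError(f"carrier_fraction in (0,1], got {self.carrier_fraction}")


def default_planted_rules() -> list[PlantedRule]:
    """Five planted rules with disjoint left-hand sides (sizes 1,1,2,2,3).

    All targets share one confidence (0.70): under independent carrier draws
    with max-confidence outcome semantics, equal targets keep each planted
    left-hand side's conditional positive rate exactly at its target, so the
    planted parameters stay identifiable from the generated data. Carrier
    fraction 0.12 gives ~2400 carriers at n=20,000, pinning the empirical
    confidence to within about ±0.03 of target.
    """
    return [
        PlantedRule(("ed_visits_ge_12",), 0.70, 0.12),
        PlantedRule(("systemic_steroid_units_ge_25",), 0.70, 0.12),
        PlantedRule(("distinct_asthma_meds_ge_21", "asthma_prescribers_ge_9"), 0.70, 0.12),
        PlantedRule(("major_asthma_visits_ge_4", "no_outpatient_visit"), 0.70, 0.12),
        PlantedRule(
            ("inpatient_los_gt_1p75_le_2p95", "health_literacy_le_244", "last_ed_visit_le_49d"),
            0.70,
            0.12,
        ),
    ]


def demo_planted_rules() -> list[PlantedRule]:
    """Sparser carriers for a strongly imbalanced end-to-end demo cohort."""
    return [
        PlantedRule(("ed_visits_ge_12",), 0.65, 0.02),
        PlantedRule(("systemic_steroid_units_ge_25",), 0.65, 0.02),
        PlantedRule(("distinct_asthma_meds_ge_21", "asthma_prescribers_ge_9"), 0.65, 0.02),
        PlantedRule(("major_asthma_visits_ge_4", "no_outpatient_visit"), 0.65, 0.02),
        PlantedRule(
            ("inpatient_los_gt_1p75_le_2p95", "health_literacy_le_244", "last_ed_visit_le_49d"),
            0.65,
            0.02,
        ),
    ]


@dataclass(frozen=True)
class CohortSpec:
    n_instances: int
    n_noise_items: int = 8
    base_positive_rate: float = 0.04
    planted_rules: tuple[PlantedRule, ...] = ()
    noise_item_prob: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "planted_rules", tuple(self.planted_rules))
        if self.n_instances < 1:
            raise ValueError("n_instances must be >= 1")
        if not 0 < self.base_positive_rate < 1:
            raise ValueError("base_positive_rate must be in (0,1)")
        if not 0 <= self.noise_item_prob <= 1:
            raise ValueError("noise_item_prob must be in [0,1]")

    def noise_item_ids(self) -> list[str]:
        return [f"noise_{j:02d}" for j in range(self.n_noise_items)]


def generate_cohort(spec: CohortSpec) -> tuple[Dataset, dict]:
    """Generate a seeded cohort and its ground truth.

    Per instance: each planted lhs is included jointly with probability
    carrier_fraction; noise items are included independently; the outcome is
    positive with the target confidence of the highest-confidence planted
    rule whose whole lhs the instance carries, else at the base rate.
    """
    noise_ids = spec.noise_item_ids()
    planted_items = sorted({i for r in spec.planted_rules for i in r.lhs})
    clash = set(planted_items) & set(noise_ids)
    if clash:
        raise ValueError(f"planted lhs items collide with noise item ids: {sorted(clash)}")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_instances
    carries = {
        id(r): rng.random(n) < r.carrier_fraction for r in spec.planted_rules
    }
    noise = rng.random((n, len(noise_ids))) < spec.noise_item_prob

    item_sets: list[set] = [set() for _ in range(n)]
    for r in spec.planted_rules:
        rows = np.flatnonzero(carries[id(r)])
        for row in rows:
            item_sets[row].update(r.lhs)
    for j, nid in enumerate(noise_ids):
        for row in np.flatnonzero(noise[:, j]):
            item_sets[row].add(nid)

    # a rule fires iff the final item set contains its whole lhs
    p_pos = np.full(n, spec.base_positive_rate)
    for r in sorted(spec.planted_rules, key=lambda r: r.target_confidence):
        lhs = set(r.lhs)
        firing = np.fromiter((lhs <= s for s in item_sets), dtype=bool, count=n)
        p_pos[firing] = r.target_confidence
    outcomes = (rng.random(n) < p_pos).astype(int)

    transactions = tuple(
        Transaction(instance_id=i, items=frozenset(item_sets[i]), outcome=int(outcomes[i]))
        for i in range(n)
    )
    dataset = Dataset(transactions, interesting_values=(POSITIVE,))
    ground_truth = {
        "spec": {
            "n_instances": spec.n_instances,
            "n_noise_items": spec.n_noise_items,
            "base_positive_rate": spec.base_positive_rate,
            "noise_item_prob": spec.noise_item_prob,
            "seed": spec.seed,
        },
        "planted_rules": [
            {
                "lhs": list(r.lhs),
                "target_confidence": r.target_confidence,
                "carrier_fraction": r.carrier_fraction,
            }
            for r in spec.planted_rules
        ],
        "positive_rate": float(outcomes.mean()),
    }
    return dataset, ground_truth


class RuleStats(NamedTuple):
    commonality: float
    confidence: float | None  # None when no instance satisfies the lhs
    support: float


def empirical_rule_stats(dataset: Dataset, rule_lhs: Sequence[str], w: object) -> RuleStats:
    """Exact commonality / confidence / support of a left-hand side.

    The empty lhs is a diagnostic query: commonality 1 and confidence equal
    to the positive rate. Confidence is None (undefined) when no instance
    satisfies the lhs.
    """
    lhs = frozenset(rule_lhs)
    n_all = len(dataset)
    s_w = dataset.s_w(w)
    if not s_w:
        raise ValueError("no instances of interesting value")
    matching = [t for t in dataset.transactions if lhs <= t.items]
    matching_w = [t for t in matching if t.outcome == w]
    commonality = len(matching_w) / len(s_w)
    confidence = len(matching_w) / len(matching) if matching else None
    support = len(matching_w) / n_all
    return RuleStats(commonality, confidence, support)


def fixture_a() -> Dataset:
    """The pinned 10-transaction worked example over items A, B, C.

    Positives (outcome 1): 1:{A,B}, 2:{A,B,C}, 3:{A}, 4:{B};
    negatives: 5:{C}, 6:{A}, 7:{A,C}, 8:{}, 9:{B,C}, 10:{A,B}.
    """
    rows = [
        (1, {"A", "B"}, 1),
        (2, {"A", "B", "C"}, 1),
        (3, {"A"}, 1),
        (4, {"B"}, 1),
        (5, {"C"}, 0),
        (6, {"A"}, 0),
        (7, {"A", "C"}, 0),
        (8, set(), 0),
        (9, {"B", "C"}, 0),
        (10, {"A", "B"}, 0),
    ]
    return Dataset(
        tuple(Transaction(i, frozenset(items), out) for i, items, out in rows),
        interesting_values=(1,),
    )


def write_cohort(dataset: Dataset, ground_truth: dict, out_dir: str | Path) -> dict[str, Path]:
    """Emit data.csv + sidecar.yaml (+ ground_truth.json) consumable by data_model.

    Each item becomes a 0/1 categorical feature whose equality-with-1 item
    reproduces the original item id, so re-encoding the CSV yields the same
    transactions.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    item_ids = dataset.vocabulary_ids()
    rows = []
    for t in dataset.transactions:
        row = {"instance_id": t.instance_id}
        row.update({iid: int(iid in t.items) for iid in item_ids})
        row["outcome"] = t.outcome
        rows.append(row)
    data_path = out / "data.csv"
    pd.DataFrame(rows).to_csv(data_path, index=False)
    sidecar = {
        "outcome": "outcome",
        "interesting_values": list(dataset.interesting_values),
        "features": [
            {"feature_id": iid, "kind": "categorical", "categories": [0, 1]}
            for iid in item_ids
        ],
        "vocabulary": [
            {"item_id": iid, "feature_id": iid, "predicate": "equals", "value": 1}
            for iid in item_ids
        ],
    }
    sidecar_path = out / "sidecar.yaml"
    sidecar_path.write_text(yaml.safe_dump(sidecar, sort_keys=False))
    paths = {"data": data_path, "sidecar": sidecar_path}
    if ground_truth is not None:
        gt_path = out / "ground_truth.json"
        gt_path.write_text(json.dumps(ground_truth, indent=1))
        paths["ground_truth"] = gt_path
    return paths
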