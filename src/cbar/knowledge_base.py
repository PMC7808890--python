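"""Clinician-compiled knowledge: allowed items and item→intervention links.

Two kinds of manually curated knowledge drive the explanation function:
which feature-value items may appear in rules (those plausibly positively
correlated with the poor outcome), and which intervention texts attach to
each actionable item. Both live in a declarative YAML/JSON file, not code.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .data_model import Transaction

__all__ = [
    "KBValidationError",
    "Intervention",
    "KnowledgeBase",
    "filter_transaction",
    "attach_interventions",
    "load_kb",
    "save_kb",
]


class KBValidationError(ValueError):
    pass


@dataclass(frozen=True)
class Intervention:
    """A recommendation linked to one actionable item."""

    intervention_id: str
    text: str
    item_id: str

    def __post_init__(self) -> None:
        if not self.text:
            raise KBValidationError(f"intervention {self.intervention_id!r} has empty text")


@dataclass(frozen=True)
class KnowledgeBase:
    allowed_items: frozenset
    interventions: Mapping[str, tuple[Intervention, ...]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "allowed_items", frozenset(self.allowed_items))
        object.__setattr__(
            self, "interventions", {k: tuple(v) for k, v in dict(self.interventions).items()}
        )
        offenders = sorted(set(self.interventions) - self.allowed_items)
        if offenders:
            raise KBValidationError(
                f"intervention-bearing items not in allowed_items: {offenders}"
            )
        for iid, ivs in self.interventions.items():
            if not ivs:
                raise KBValidationError(f"item {iid!r} maps to an empty intervention list")
            for iv in ivs:
                if iv.item_id != iid:
                    raise KBValidationError(
                        f"intervention {iv.intervention_id!r} linked to {iv.item_id!r} "
                        f"but filed under {iid!r}"
                    )

    def validate_against(self, vocabulary_ids: Iterable[str]) -> None:
        """Every referenced item must exist in the vocabulary."""
        vocab = set(vocabulary_ids)
        offenders = sorted(self.allowed_items - vocab)
        if offenders:
            raise KBValidationError(f"KB references undeclared items: {offenders}")

    def interventions_for(self, item_id: str) -> tuple[Intervention, ...]:
        return self.interventions.get(item_id, ())


def filter_transaction(t: Transaction, kb: KnowledgeBase) -> Transaction:
    """Drop from a transaction the items not marked as allowed; idempotent."""
    return Transaction(t.instance_id, t.items & kb.allowed_items, t.outcome)


def attach_interventions(rule, kb: KnowledgeBase):
    """Connect to a rule the interventions linked to its left-hand-side items.

    The rule is actionable iff at least one intervention attaches. Statistics
    (commonality, confidence, support) are untouched.
    """
    ivs: list[Intervention] = []
    for item_id in sorted(rule.lhs):
        ivs.extend(kb.interventions_for(item_id))
    return dataclasses.replace(rule, interventions=tuple(ivs), actionable=bool(ivs))


def _kb_to_dict(kb: KnowledgeBase) -> dict:
    return {
        "allowed_items": sorted(kb.allowed_items),
        "interventions": [
            {"intervention_id": iv.intervention_id, "item_id": iv.item_id, "text": iv.text}
            for iid in sorted(kb.interventions)
            for iv in kb.interventions[iid]
        ],
    }


def _kb_from_dict(raw: Mapping) -> KnowledgeBase:
    allowed = frozenset(raw.get("allowed_items", ()))
    by_item: dict[str, list[Intervention]] = {}
    for d in raw.get("interventions", ()):
        iv = Intervention(d["intervention_id"], d["text"], d["item_id"])
        by_item.setdefault(iv.item_id, []).append(iv)
    return KnowledgeBase(allowed, {k: tuple(v) for k, v in by_item.items()})


def save_kb(kb: KnowledgeBase, path: str | Path) -> None:
    path = Path(path)
    d = _kb_to_dict(kb)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(d, indent=1, ensure_ascii=False))
    else:
        path.write_text(yaml.safe_dump(d, allow_unicode=True, sort_keys=False))


def load_kb(path: str | Path) -> KnowledgeBase:
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    return _kb_from_dict(raw)
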