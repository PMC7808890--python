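"""Rule-formed explanations for flagged instances.

For an instance the black-box model flags as high risk, every retained rule
whose whole left-hand side the instance satisfies is listed as one reason;
interventions linked to actionable items on those rules are displayed beside
them. Rules are ordered by a greedy diversification: the highest-confidence
rule first, thereafter the rule covering the most not-yet-seen items, so the
top few rules carry nonredundant information.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .data_model import Item, Transaction
from .knowledge_base import KnowledgeBase
from .rule_miner import Rule

__all__ = ["Explanation", "fits", "explain_instance", "diversify_rules", "explanations_to_jsonl"]


@dataclass(frozen=True)
class Explanation:
    instance_id: object
    fitting_rules: tuple[Rule, ...]  # diversification order
    n_rules: int
    n_actionable_rules: int
    distinct_actionable_items: frozenset
    interventions: tuple  # deduplicated; each Intervention carries its item_id
    display_top_n: int

    def to_dict(self, vocabulary: Mapping[str, Item] | None = None) -> dict:
        return {
            "instance_id": self.instance_id,
            "n_rules": self.n_rules,
            "n_actionable_rules": self.n_actionable_rules,
            "distinct_actionable_items": sorted(self.distinct_actionable_items),
            "interventions": [
                {"intervention_id": iv.intervention_id, "item_id": iv.item_id, "text": iv.text}
                for iv in self.interventions
            ],
            "display_top_n": self.display_top_n,
            "rules": [
                dict(r.to_dict(), rendering=r.render(vocabulary)) for r in self.fitting_rules
            ],
        }


def fits(rule: Rule, t: Transaction) -> bool:
    """A rule fits an instance iff the instance fulfils its whole lhs."""
    return rule.lhs <= t.items


def diversify_rules(fitting_rules: Sequence[Rule], top_n: int = 3) -> list[Rule]:
    """Greedy nonredundancy ordering of the rules fitting one instance.

    First the highest-confidence rule; each subsequent pick maximizes the
    number of lhs items not yet covered, with ties broken by higher
    confidence, then smaller lhs, then lexicographic lhs. The full ordering
    is returned; callers display the first top_n by default.
    """
    if top_n < 1:
        raise ValueError(f"top_n must be >= 1, got {top_n}")
    remaining = list(fitting_rules)
    ordered: list[Rule] = []
    covered: set = set()
    while remaining:
        if not ordered:
            key = lambda r: (-r.confidence, len(r.lhs), tuple(sorted(r.lhs)))
        else:
            key = lambda r: (
                -len(r.lhs - covered),
                -r.confidence,
                len(r.lhs),
                tuple(sorted(r.lhs)),
            )
        best = min(remaining, key=key)
        remaining.remove(best)
        ordered.append(best)
        covered |= best.lhs
    return ordered


def explain_instance(
    t: Transaction,
    rules: Sequence[Rule],
    kb: KnowledgeBase | None = None,
    top_n: int = 3,
) -> Explanation:
    """List, order and annotate the retained rules fitting one instance.

    ``rules`` is the retained, intervention-attached rule set for the
    interesting value predicted for the instance; an empty explanation is a
    legitimate outcome (rare-reason instances fit no rule). When a knowledge
    base is passed, actionability is resolved from it for rules that carry no
    attached interventions.
    """
    fitting = [r for r in rules if fits(r, t)]
    ordered = diversify_rules(fitting, top_n) if fitting else []
    interventions = []
    seen = set()
    actionable_items: set = set()
    n_actionable = 0
    for r in ordered:
        ivs = r.interventions
        if not ivs and kb is not None:
            ivs = tuple(iv for iid in sorted(r.lhs) for iv in kb.interventions_for(iid))
        if ivs:
            n_actionable += 1
        for iv in ivs:
            actionable_items.add(iv.item_id)
            if iv.intervention_id not in seen:
                seen.add(iv.intervention_id)
                interventions.append(iv)
    return Explanation(
        instance_id=t.instance_id,
        fitting_rules=tuple(ordered),
        n_rules=len(ordered),
        n_actionable_rules=n_actionable,
        distinct_actionable_items=frozenset(actionable_items),
        interventions=tuple(interventions),
        display_top_n=min(top_n, len(ordered)),
    )


def explanations_to_jsonl(
    explanations: Sequence[Explanation],
    path: str | Path,
    vocabulary: Mapping[str, Item] | None = None,
) -> None:
    with open(path, "w") as fh:
        for e in explanations:
            fh.write(json.dumps(e.to_dict(vocabulary)) + "\n")
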