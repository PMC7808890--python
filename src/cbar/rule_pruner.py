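"""Rule-set reduction: generality pruning, allowed-item filtering, τ curve.

A specific rule is dominated when some strictly more general mined rule with
the same right-hand side has confidence within τ of it; dominated rules are
dropped with the dominating rule recorded as witness. The number of retained
rules as a function of τ is non-increasing and typically flattens to an
asymptote — the elbow of that curve is the recommended place to set τ.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Sequence

from .knowledge_base import KnowledgeBase
from .rule_miner import Rule

__all__ = [
    "PruneReport",
    "prune_by_generality",
    "filter_rules_by_allowed_items",
    "rules_vs_tau_curve",
    "curve_to_csv",
]

DEFAULT_TAU = 0.15


@dataclass(frozen=True)
class PruneReport:
    retained: tuple[Rule, ...]
    dropped: tuple[tuple[Rule, Rule], ...]  # (specific rule, witnessing general rule)
    tau: float

    def to_dict(self) -> dict:
        return {
            "tau": self.tau,
            "n_input": len(self.retained) + len(self.dropped),
            "n_retained": len(self.retained),
            "n_dropped": len(self.dropped),
            "retained": [r.to_dict() for r in self.retained],
            "dropped": [
                {"rule": spec.to_dict(), "witness": wit.to_dict()}
                for spec, wit in self.dropped
            ],
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def prune_by_generality(rules: Sequence[Rule], tau: float) -> PruneReport:
    """Drop each rule dominated within τ by a strictly more general mined rule.

    A rule l2 is dropped iff some mined rule l1 with the same rhs satisfies
    lhs(l1) ⊊ lhs(l2) and confidence(l1) >= confidence(l2) - τ. Every mined
    general rule is eligible as witness, whether or not it is itself dropped,
    which makes the result independent of processing order. Among multiple
    witnesses the one with the highest confidence (ties: smaller, then
    lexicographically smallest lhs) is recorded.
    """
    if tau < 0:
        raise ValueError(f"tau must be >= 0, got {tau}")
    by_key: dict[tuple, Rule] = {}
    for r in rules:
        by_key[(r.rhs, r.lhs)] = r
    retained: list[Rule] = []
    dropped: list[tuple[Rule, Rule]] = []
    for r in rules:
        witnesses: list[Rule] = []
        lhs = sorted(r.lhs)
        for size in range(1, len(lhs)):
            for sub in combinations(lhs, size):
                general = by_key.get((r.rhs, frozenset(sub)))
                if general is not None and general.confidence >= r.confidence - tau:
                    witnesses.append(general)
        if witnesses:
            witnesses.sort(key=lambda g: (-g.confidence, len(g.lhs), tuple(sorted(g.lhs))))
            dropped.append((r, witnesses[0]))
        else:
            retained.append(r)
    return PruneReport(tuple(retained), tuple(dropped), tau)


def filter_rules_by_allowed_items(rules: Sequence[Rule], kb: KnowledgeBase) -> list[Rule]:
    """Keep exactly the rules whose whole left-hand side is allowed."""
    return [r for r in rules if r.lhs <= kb.allowed_items]


def rules_vs_tau_curve(
    rules: Sequence[Rule], tau_grid: Sequence[float]
) -> list[tuple[float, int]]:
    """Retained-rule count at each τ of a non-empty, non-negative grid."""
    grid = list(tau_grid)
    if not grid:
        raise ValueError("tau_grid must be non-empty")
    if any(t < 0 for t in grid):
        raise ValueError("tau_grid values must be >= 0")
    return [(t, len(prune_by_generality(rules, t).retained)) for t in grid]


def curve_to_csv(curve: Sequence[tuple[float, int]], path: str | Path) -> None:
    lines = ["tau,rules_remaining"]
    lines += [f"{t},{n}" for t, n in curve]
    Path(path).write_text("\n".join(lines) + "\n")
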