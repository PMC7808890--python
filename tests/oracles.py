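"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's mining/pruning code paths: counting is
a per-transaction subset test, thresholds are compared in exact rational
arithmetic, and pruning is a quadratic all-pairs scan.
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import combinations


def naive_match_count(itemset, transactions) -> int:
    s = frozenset(itemset)
    return sum(1 for t in transactions if s <= t.items)


def brute_force_mine(dataset, w, m_min, c_min, l_max, vocabulary=None):
    """Enumerate every itemset up to l_max; full naive counting.

    Returns {lhs: (commonality, confidence)} for the retained rules.
    """
    txs = list(dataset.transactions)
    s_w = [t for t in txs if t.outcome == w]
    if vocabulary is None:
        vocabulary = sorted({i for t in txs for i in t.items})
    out = {}
    for k in range(1, l_max + 1):
        for combo in combinations(sorted(vocabulary), k):
            lhs = frozenset(combo)
            c_w = naive_match_count(lhs, s_w)
            if Fraction(c_w, len(s_w)) < Fraction(m_min):
                continue
            c_all = naive_match_count(lhs, txs)
            if c_all == 0 or Fraction(c_w, c_all) < Fraction(c_min):
                continue
            out[lhs] = (c_w / len(s_w), c_w / c_all)
    return out


def full_count_confidence_decision(itemset, w, dataset, c_min):
    """(accepted, confidence, l_w, l_not_w) by exhaustive counting."""
    lhs = frozenset(itemset)
    l_w = sum(1 for t in dataset.transactions if t.outcome == w and lhs <= t.items)
    l_not_w = sum(1 for t in dataset.transactions if t.outcome != w and lhs <= t.items)
    if l_w == 0:
        return False, 0.0, l_w, l_not_w
    accepted = Fraction(l_w, l_w + l_not_w) >= Fraction(c_min)
    return accepted, l_w / (l_w + l_not_w), l_w, l_not_w


def prune_all_pairs(rules, tau):
    """Quadratic generality-pruning oracle: returns the retained lhs sets."""
    retained = []
    for r2 in rules:
        dominated = any(
            r1.rhs == r2.rhs
            and r1.lhs < r2.lhs
            and r1.confidence >= r2.confidence - tau
            for r1 in rules
        )
        if not dominated:
            retained.append(r2)
    return {(r.rhs, r.lhs) for r in retained}


def entropy_bits(labels) -> float:
    n = len(labels)
    if n == 0:
        return 0.0
    counts = {}
    for x in labels:
        counts[x] = counts.get(x, 0) + 1
    return -sum(c / n * math.log2(c / n) for c in counts.values())


def information_gain_bits(feature_values, labels) -> float:
    n = len(labels)
    groups = {}
    for f, y in zip(feature_values, labels):
        groups.setdefault(f, []).append(y)
    cond = sum(len(g) / n * entropy_bits(g) for g in groups.values())
    return entropy_bits(labels) - cond
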