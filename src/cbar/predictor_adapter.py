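"""Interface to any black-box risk model.

The predictive model stays external: this module ingests its per-instance
risk scores, turns a top-fraction cutoff into binary flags (the instances
"predicted to have the poor outcome"), and ranks features either from an
externally supplied importance file or by information gain. A small
regularized logistic scorer is included so end-to-end demos need no external
model.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data_model import Dataset

__all__ = [
    "RiskScore",
    "CutoffResult",
    "top_fraction_cutoff",
    "rank_features_information_gain",
    "select_top_features",
    "item_membership_frame",
    "ReferenceScorer",
    "load_scores",
    "save_scores",
    "save_flags",
    "load_flags",
    "load_importance",
]


@dataclass(frozen=True)
class RiskScore:
    instance_id: object
    score: float


@dataclass(frozen=True)
class CutoffResult:
    flagged: frozenset
    fraction: float
    threshold: float


def top_fraction_cutoff(scores: Sequence[RiskScore], fraction: float) -> CutoffResult:
    """Flag exactly ceil(fraction*N) instances with the largest scores.

    Ties at the boundary are broken by ascending instance_id, so the result
    is deterministic and independent of input order.
    """
    if not scores:
        raise ValueError("scores must be non-empty")
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0,1], got {fraction}")
    ids = [s.instance_id for s in scores]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate instance_id in scores")
    if any(not math.isfinite(s.score) for s in scores):
        raise ValueError("scores must be finite")
    k = math.ceil(fraction * len(scores))
    ranked = sorted(scores, key=lambda s: (-s.score, s.instance_id))
    return CutoffResult(
        flagged=frozenset(s.instance_id for s in ranked[:k]),
        fraction=fraction,
        threshold=ranked[k - 1].score,
    )


def _entropy(counts: np.ndarray) -> float:
    """Shannon entropy in bits of a count vector."""
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def rank_features_information_gain(
    features: pd.DataFrame, outcome: Sequence
) -> list[tuple[str, float]]:
    """Rank categorical/boolean feature columns by information gain (bits).

    gain(f) = H(outcome) - H(outcome | f); descending, ties broken by
    feature_id. A degenerate (single-class) outcome yields all-zero gains
    with a warning.
    """
    y = pd.Series(list(outcome))
    if len(y) != len(features):
        raise ValueError("outcome length does not match features")
    h_y = _entropy(y.value_counts().to_numpy())
    if h_y == 0.0:
        warnings.warn("outcome has a single class: all information gains are 0")
        return sorted((str(c), 0.0) for c in features.columns)
    gains = []
    for col in features.columns:
        f = features[col].astype(object).where(features[col].notna(), "(missing)")
        cond = 0.0
        for _, sub in y.groupby(f.to_numpy()):
            cond += len(sub) / len(y) * _entropy(sub.value_counts().to_numpy())
        gains.append((str(col), h_y - cond))
    gains.sort(key=lambda kv: (-kv[1], kv[0]))
    return gains


def select_top_features(ranking: Sequence[tuple[str, float]], k: int) -> list[str]:
    """First min(k, |ranking|) feature ids of a (feature, score) ranking."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    return [f for f, _ in ranking[:k]]


def item_membership_frame(
    dataset: Dataset, vocabulary: Iterable[str] | None = None
) -> tuple[pd.DataFrame, pd.Series]:
    """Boolean item-membership matrix and outcome vector for a dataset."""
    items = sorted(vocabulary) if vocabulary is not None else dataset.vocabulary_ids()
    data = {
        iid: [iid in t.items for t in dataset.transactions] for iid in items
    }
    X = pd.DataFrame(data, index=[t.instance_id for t in dataset.transactions])
    y = pd.Series([t.outcome for t in dataset.transactions], index=X.index)
    return X, y


class ReferenceScorer:
    """Regularized additive logistic scorer over item membership.

    A convenience stand-alone risk model for demos and synthetic studies; any
    external model's scores can be supplied instead via a CSV.
    """

    def __init__(self, C: float = 1.0, seed: int = 0):
        self.C = C
        self.seed = seed
        self._model = None
        self._items: list[str] = []

    def fit(self, dataset: Dataset, w: object) -> "ReferenceScorer":
        from sklearn.linear_model import LogisticRegression

        X, y = item_membership_frame(dataset)
        self._items = list(X.columns)
        self._model = LogisticRegression(
            C=self.C, max_iter=1000, random_state=self.seed
        ).fit(X.to_numpy(), (y == w).to_numpy())
        return self

    def score(self, dataset: Dataset) -> list[RiskScore]:
        if self._model is None:
            raise RuntimeError("scorer is not fitted")
        X, _ = item_membership_frame(dataset, vocabulary=self._items)
        X = X[self._items]
        p = self._model.predict_proba(X.to_numpy())[:, 1]
        return [
            RiskScore(t.instance_id, float(pi))
            for t, pi in zip(dataset.transactions, p)
        ]


def save_scores(scores: Sequence[RiskScore], path: str | Path) -> None:
    pd.DataFrame(
        {"instance_id": [s.instance_id for s in scores], "score": [s.score for s in scores]}
    ).to_csv(path, index=False, float_format="%.17g")


def load_scores(path: str | Path) -> list[RiskScore]:
    df = pd.read_csv(path, float_precision="round_trip")
    return [RiskScore(r.instance_id, float(r.score)) for r in df.itertuples(index=False)]


def save_flags(cutoff: CutoffResult, all_ids: Sequence, path: str | Path) -> None:
    pd.DataFrame(
        {
            "instance_id": list(all_ids),
            "flagged": [int(i in cutoff.flagged) for i in all_ids],
        }
    ).to_csv(path, index=False)


def load_flags(path: str | Path) -> set:
    df = pd.read_csv(path)
    return set(df.loc[df.flagged.astype(bool), "instance_id"])


def load_importance(path: str | Path) -> list[tuple[str, float]]:
    """External importance ranking CSV: feature_id, importance (descending)."""
    df = pd.read_csv(path)
    pairs = [(str(a), float(b)) for a, b in zip(df.iloc[:, 0], df.iloc[:, 1])]
    pairs.sort(key=lambda kv: (-kv[1], kv[0]))
    return pairs
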