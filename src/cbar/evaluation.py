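"""Performance metrics for the explanation function.

Headline metric: among the instances the risk model flagged and that truly
have the poor outcome, the percentage with at least one fitting retained rule
(explanation coverage), reported to one decimal. Secondary views: coverage
over all poor-outcome instances, per-instance rule/actionable-rule/
actionable-item counts with mean and sample SD, and their integer histograms.
"""

from __future__ import annotations

import json
import statistics
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .explainer import Explanation

__all__ = [
    "coverage_pct",
    "CoverageReport",
    "explanation_coverage",
    "per_patient_counts",
    "count_distributions",
    "build_coverage_report",
]


def coverage_pct(numerator: int, denominator: int) -> float | None:
    """round(100*x/n, 1); None (not applicable) when the denominator is 0."""
    if denominator == 0:
        return None
    return round(100.0 * numerator / denominator, 1)


def per_patient_counts(explanation: Explanation) -> tuple[int, int, int]:
    """(n_rules, n_actionable_rules, n_distinct_actionable_items)."""
    return (
        explanation.n_rules,
        explanation.n_actionable_rules,
        len(explanation.distinct_actionable_items),
    )


def explanation_coverage(
    explanations: Mapping[object, Explanation], flagged_correct_ids: Iterable
) -> dict:
    """Coverage fragment over the flagged, correctly predicted instances.

    Every flagged-correct id must have an explanation record (possibly
    empty). "Explained" means at least one fitting retained rule; coverage
    confined to actionable rules is reported alongside.
    """
    ids = list(flagged_correct_ids)
    missing = [i for i in ids if i not in explanations]
    if missing:
        raise KeyError(f"no explanation record for flagged-correct ids: {missing[:5]}")
    n = len(ids)
    n_explained = sum(1 for i in ids if explanations[i].n_rules > 0)
    n_actionable = sum(1 for i in ids if explanations[i].n_actionable_rules > 0)
    return {
        "n_flagged_correct": n,
        "n_explained": n_explained,
        "coverage_pct": coverage_pct(n_explained, n),
        "n_explained_actionable": n_actionable,
        "coverage_actionable_pct": coverage_pct(n_actionable, n),
    }


def count_distributions(explanations: Iterable[Explanation]) -> dict[str, dict[int, int]]:
    """Integer-binned histograms of the three per-instance counts."""
    hists = {
        "n_rules": Counter(),
        "n_actionable_rules": Counter(),
        "n_distinct_actionable_items": Counter(),
    }
    for e in explanations:
        r, a, i = per_patient_counts(e)
        hists["n_rules"][r] += 1
        hists["n_actionable_rules"][a] += 1
        hists["n_distinct_actionable_items"][i] += 1
    return {k: dict(sorted(v.items())) for k, v in hists.items()}


def _mean_sd(values: Sequence[int]) -> tuple[float | None, float | None]:
    if not values:
        return None, None
    mean = round(statistics.fmean(values), 2)
    sd = round(statistics.stdev(values), 2) if len(values) > 1 else None
    return mean, sd


@dataclass(frozen=True)
class CoverageReport:
    n_flagged_correct: int
    n_explained: int
    coverage_pct: float | None
    n_explained_actionable: int
    coverage_actionable_pct: float | None
    n_all_positive: int | None
    n_all_positive_explained: int | None
    coverage_all_positive_pct: float | None
    mean_n_rules: float | None
    sd_n_rules: float | None
    mean_n_actionable_rules: float | None
    sd_n_actionable_rules: float | None
    mean_n_distinct_actionable_items: float | None
    sd_n_distinct_actionable_items: float | None
    histograms: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["histograms"] = {
            k: {str(b): c for b, c in v.items()} for k, v in self.histograms.items()
        }
        return d

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def build_coverage_report(
    explanations: Mapping[object, Explanation],
    flagged_correct_ids: Iterable,
    all_positive_explanations: Mapping[object, Explanation] | None = None,
) -> CoverageReport:
    """Assemble the full report.

    ``explanations`` covers the flagged instances; count statistics and
    histograms are computed over the flagged-correct instances (mean/SD over
    the explained ones, mirroring per-patient reporting). When explanations
    for *all* poor-outcome instances are supplied, overall coverage of the
    positives is reported too.
    """
    frag = explanation_coverage(explanations, flagged_correct_ids)
    ids = list(flagged_correct_ids)
    expl = [explanations[i] for i in ids]
    counts = [per_patient_counts(e) for e in expl]
    explained_counts = [c for c in counts if c[0] > 0]
    mean_r, sd_r = _mean_sd([c[0] for c in explained_counts])
    mean_a, sd_a = _mean_sd([c[1] for c in explained_counts])
    mean_i, sd_i = _mean_sd([c[2] for c in explained_counts])
    n_pos = n_pos_explained = cov_pos = None
    if all_positive_explanations is not None:
        n_pos = len(all_positive_explanations)
        n_pos_explained = sum(
            1 for e in all_positive_explanations.values() if e.n_rules > 0
        )
        cov_pos = coverage_pct(n_pos_explained, n_pos)
    return CoverageReport(
        n_flagged_correct=frag["n_flagged_correct"],
        n_explained=frag["n_explained"],
        coverage_pct=frag["coverage_pct"],
        n_explained_actionable=frag["n_explained_actionable"],
        coverage_actionable_pct=frag["coverage_actionable_pct"],
        n_all_positive=n_pos,
        n_all_positive_explained=n_pos_explained,
        coverage_all_positive_pct=cov_pos,
        mean_n_rules=mean_r,
        sd_n_rules=sd_r,
        mean_n_actionable_rules=mean_a,
        sd_n_actionable_rules=sd_a,
        mean_n_distinct_actionable_items=mean_i,
        sd_n_distinct_actionable_items=sd_i,
        histograms=count_distributions(expl),
    )
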