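"""Config-driven end-to-end runs: encode → mine → prune → flag → explain → evaluate.

Inputs are delimited text (data CSV/TSV + YAML sidecar, optional KB file,
optional external score CSV); outputs are a reproducible artifact bundle
(rules.jsonl, prune_report.json, flags.csv, explanations.jsonl,
coverage.json, curve.csv, run_log.json, effective_config.yaml). All artifacts
are written atomically, and identical config+seed yields identical artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from . import evaluation, explainer, predictor_adapter, rule_miner, rule_pruner
from .data_model import load_sidecar, load_table
from .knowledge_base import KnowledgeBase, load_kb
from .rule_miner import MiningParams

__all__ = ["ConfigError", "PipelineConfig", "run_pipeline"]

DEFAULT_TAU_GRID = [0.0, 0.05, 0.10, 0.15, 0.20, 0.25, 0.30]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PipelineConfig:
    data: str
    sidecar: str
    out_dir: str
    kb: str | None = None
    scores: str | None = None  # None -> fit the reference scorer on the data
    m_min: float = 0.002
    c_min: float = 0.5
    l_max: int = 5
    tau: float = 0.15
    s_min: float | None = None
    sample_fraction: float = 1.0
    cutoff_fraction: float = 0.1
    kb_application: str = "pre_mining"
    top_features: int | None = None
    importance: str | None = None  # external feature-importance CSV
    top_n_display: int = 3
    seed: int = 0

    def mining_params(self) -> MiningParams:
        return MiningParams(
            m_min=self.m_min,
            c_min=self.c_min,
            l_max=self.l_max,
            tau=self.tau,
            s_min=self.s_min,
            sample_fraction=self.sample_fraction,
            seed=self.seed,
        )

    def validate(self) -> None:
        try:
            self.mining_params()
        except rule_miner.ParameterError as exc:
            raise ConfigError(str(exc)) from exc
        if not 0 < self.cutoff_fraction <= 1:
            raise ConfigError(f"cutoff_fraction must be in (0,1], got {self.cutoff_fraction}")
        if self.kb_application not in ("pre_mining", "post_mining"):
            raise ConfigError(f"bad kb_application {self.kb_application!r}")
        if self.top_features is not None and self.top_features < 1:
            raise ConfigError("top_features must be >= 1")
        for label, p in (("data", self.data), ("sidecar", self.sidecar), ("kb", self.kb),
                         ("scores", self.scores), ("importance", self.importance)):
            if p is not None and not Path(p).exists():
                raise ConfigError(f"{label} path does not exist: {p}")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)


def _atomic_write(path: Path, writer) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    writer(tmp)
    os.replace(tmp, path)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the run log as a dict.

    Fails before any artifact is written when the config is invalid or an
    input path is missing.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    dataset = load_table(config.data, config.sidecar)
    schema, vocabulary, _, interesting = load_sidecar(config.sidecar)
    if len(interesting) != 1:
        raise ConfigError("pipeline requires exactly one interesting outcome value")
    w = interesting[0]
    vocab_by_id = {it.item_id: it for it in vocabulary}

    kb = load_kb(config.kb) if config.kb else None
    if kb is not None:
        kb.validate_against(vocab_by_id)

    vocab_ids: Sequence[str] = list(vocab_by_id)
    n_features_used = len({it.feature_id for it in vocabulary})
    if config.top_features is not None:
        if config.importance:
            ranking = predictor_adapter.load_importance(config.importance)
        else:
            X, y = predictor_adapter.item_membership_frame(dataset)
            feat_of = {iid: vocab_by_id[iid].feature_id for iid in X.columns if iid in vocab_by_id}
            per_feature = {}
            for iid, gain in predictor_adapter.rank_features_information_gain(X, y == w):
                f = feat_of.get(iid, iid)
                per_feature[f] = max(per_feature.get(f, 0.0), gain)
            ranking = sorted(per_feature.items(), key=lambda kv: (-kv[1], kv[0]))
        top = set(predictor_adapter.select_top_features(ranking, config.top_features))
        vocab_ids = [iid for iid in vocab_ids if vocab_by_id[iid].feature_id in top]
        n_features_used = len(top & {it.feature_id for it in vocabulary})

    params = config.mining_params()
    mined = rule_miner.mine_class_rules(
        dataset, w, params, kb=kb, vocabulary=vocab_ids, kb_application=config.kb_application
    )
    report = rule_pruner.prune_by_generality(mined, config.tau)
    retained = list(report.retained)
    if kb is not None and config.kb_application == "post_mining":
        retained = rule_pruner.filter_rules_by_allowed_items(retained, kb)
    curve = rule_pruner.rules_vs_tau_curve(mined, DEFAULT_TAU_GRID)

    if config.scores:
        scores = predictor_adapter.load_scores(config.scores)
    else:
        scorer = predictor_adapter.ReferenceScorer(seed=config.seed).fit(dataset, w)
        scores = scorer.score(dataset)
    cutoff = predictor_adapter.top_fraction_cutoff(scores, config.cutoff_fraction)

    by_id = {t.instance_id: t for t in dataset.transactions}
    flagged_ids = sorted(cutoff.flagged, key=str)
    explanations = {
        i: explainer.explain_instance(by_id[i], retained, kb, top_n=config.top_n_display)
        for i in flagged_ids
    }
    flagged_correct = [i for i in flagged_ids if by_id[i].outcome == w]
    positive_ids = [t.instance_id for t in dataset.transactions if t.outcome == w]
    all_positive_expl = {
        i: explanations.get(i)
        or explainer.explain_instance(by_id[i], retained, kb, top_n=config.top_n_display)
        for i in positive_ids
    }
    cov = evaluation.build_coverage_report(explanations, flagged_correct, all_positive_expl)

    log = {
        "seed": config.seed,
        "parameters": {
            "m_min": config.m_min,
            "c_min": config.c_min,
            "l_max": config.l_max,
            "tau": config.tau,
            "cutoff_fraction": config.cutoff_fraction,
            "kb_application": config.kb_application,
            "sample_fraction": config.sample_fraction,
            "top_features": config.top_features,
        },
        "n_instances": len(dataset),
        "n_positive": len(positive_ids),
        "n_features_used": n_features_used,
        "n_items_used": len(vocab_ids),
        "rule_funnel": {
            "mined": len(mined),
            "after_tau_prune": len(report.retained),
            "after_kb_filter": len(retained),
            "actionable": sum(1 for r in retained if r.actionable),
        },
        "n_flagged": len(flagged_ids),
        "n_flagged_correct": len(flagged_correct),
        "coverage_pct": cov.coverage_pct,
        "coverage_all_positive_pct": cov.coverage_all_positive_pct,
    }

    _atomic_write(out / "rules.jsonl", lambda p: rule_miner.rules_to_jsonl(retained, p))
    _atomic_write(out / "prune_report.json", lambda p: report.save(p))
    _atomic_write(out / "curve.csv", lambda p: rule_pruner.curve_to_csv(curve, p))
    _atomic_write(
        out / "flags.csv",
        lambda p: predictor_adapter.save_flags(
            cutoff, [t.instance_id for t in dataset.transactions], p
        ),
    )
    _atomic_write(
        out / "explanations.jsonl",
        lambda p: explainer.explanations_to_jsonl(
            [explanations[i] for i in flagged_ids], p, vocab_by_id
        ),
    )
    _atomic_write(out / "coverage.json", lambda p: cov.save(p))
    _atomic_write(out / "run_log.json", lambda p: Path(p).write_text(json.dumps(log, indent=1)))
    _atomic_write(out / "effective_config.yaml", lambda p: config.to_yaml(p))
    return log
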