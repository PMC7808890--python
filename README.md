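# cbar — class-based association rules for explaining black-box risk predictions

`cbar` mines class-based association rules from imbalanced clinical tabular
data and uses them to explain, instance by instance, why an external risk
model flagged someone as high risk — and which clinician-compiled
interventions apply. It is aimed at care-management settings (e.g. predicting
asthma hospital visits, readmissions) where the accurate model is a black box
but its users need reasons and actionable next steps.

## The method

Each rule has the form

```
q1 AND q2 AND … AND qn → w
```

where every item `qi` is a feature-value predicate (equality, one-sided
threshold, or interval such as "length of stay is >1.75 and ≤2.95 days") and
`w` is an *interesting* value of the outcome variable — typically the rare,
poor outcome. For a rule `l` with left-hand side `L`:

- **support(l)** = P(L and w): fraction of all instances satisfying `L` and
  linking to `w`;
- **confidence(l)** = P(w | L): the rule's precision;
- **commonality(l)** = P(L | w): value-specific support — of the instances
  linking to `w`, the fraction satisfying `L`.

On imbalanced data a plain minimum-support gate either starves the rare class
of rules or floods the miner with intermediates. `cbar` instead gates on a
minimum commonality `m_min` and a minimum confidence `c_min`, mined in two
steps:

1. **Frequent itemsets on S_w.** Apriori-style level-wise search over only
   the instances linking to `w`, where commonality is just support and is
   anti-monotone: this is equivalent to support-threshold mining on all
   instances at `m_min·|S_w|/|S_all|`, but far cheaper when `w` is rare.
2. **Confidence verification on S_all with early termination.** With `l_w`
   matches inside S_w, the scan over S_¬w stops as soon as the running match
   count exceeds `T_l = l_w·(1−c_min)/c_min`, at which point
   `confidence < c_min` is certain. Counting uses a bitmap index (one bit
   vector per item; AND + popcount).

Retained rules are then pruned for generality: a specific rule is dropped
whenever a strictly more general rule with the same right-hand side has
confidence within `τ` of it (`τ` is read off the rules-remaining-vs-τ curve,
which flattens to an asymptote). A clinician-maintained knowledge base
restricts which items may appear in rules and links interventions to
actionable items. At prediction time, the top fraction (default 10%) of
instances by external risk score are flagged, each flagged instance is
explained by the retained rules it fits (ordered by a greedy diversification
so the top few rules are non-redundant), and explanation coverage plus
per-instance rule-count distributions are reported.

## Worked example

A pinned ten-transaction dataset over items A, B, C (four instances link to
the poor outcome `w = 1`) is bundled for experimentation:

```python
from cbar import MiningParams, mine_class_rules, prune_by_generality, explain_instance
from cbar.knowledge_base import KnowledgeBase, Intervention
from cbar.synthetic_cohort import fixture_a

ds = fixture_a()
kb = KnowledgeBase(
    allowed_items=frozenset({"A", "B", "C"}),
    interventions={"A": (Intervention("I1", "reduce A exposure", "A"),),
                   "B": (Intervention("I2", "address B", "B"),)},
)
params = MiningParams(m_min=0.5, c_min=0.5, l_max=2, tau=0.15)
mined = mine_class_rules(ds, 1, params, kb=kb)
for r in mined:
    print(r.render())
```

prints the three rules meeting both gates, with their exact statistics:

```
A → 1 (confidence 0.500, commonality 0.750)
B → 1 (confidence 0.600, commonality 0.750)
A AND B → 1 (confidence 0.667, commonality 0.500)
```

`A` appears in 3 of the 4 poor-outcome instances (commonality 0.75) and in 6
instances overall, 3 of them poor (confidence 0.50). Pruning at τ = 0.15 then
drops the specific rule:

```python
report = prune_by_generality(mined, params.tau)
# retained: [['A'], ['B']]
# dropped ['A', 'B'] (witness ['B'], confidence 0.6)
```

because the more general `B → 1` (confidence 0.60) is within 0.15 of
`A AND B → 1` (confidence 0.667). Explaining instance 2 ({A, B, C}) against
the retained rules:

```python
e = explain_instance(ds.transactions[1], report.retained, kb)
# e.n_rules = 2, e.n_actionable_rules = 2, distinct actionable items {'A', 'B'}
# interventions: B: address B / A: reduce A exposure
```

The same flow runs from the shell on synthetic cohorts:

```
cbar simulate --n 20000 --seed 1 --profile demo --out cohort
cbar run-all --data cohort/data.csv --sidecar cohort/sidecar.yaml \
     --m-min 0.02 --c-min 0.5 --l-max 3 --seed 1 --out bundle
```

which writes `rules.jsonl`, `prune_report.json`, `curve.csv`, `flags.csv`,
`explanations.jsonl`, `coverage.json` and a run log with the rule funnel
(mined → τ-pruned → KB-filtered → actionable). An example knowledge base for
an asthma cohort is in `examples/asthma_kb.yaml`.

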