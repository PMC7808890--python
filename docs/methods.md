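# Methods

## Model and procedure

`cbar` treats explanation and prediction as two separate models. The first
model — any external classifier producing a risk score per instance — makes
the predictions; its accuracy is untouched. The second model is a set of
class-based association rules `q1 AND … AND qn → w` mined from historical
data for each *interesting* outcome value `w` (usually the rare poor
outcome), used only to explain the first model's flagged predictions and to
surface interventions.

For a rule with left-hand side `L`, three statistics are defined on a dataset
S_all with positive part S_w: support = P(L, w), confidence = P(w | L), and
commonality = P(L | w). Rules are retained when commonality ≥ m_min and
confidence ≥ c_min. Commonality rather than support is the frequency gate
because on imbalanced data any support threshold small enough to admit rules
for the rare class admits an enormous intermediate search space for the
common class as well.

Mining proceeds in two steps:

1. Frequent-itemset search over S_w only, where commonality is ordinary
   support and is anti-monotone in the itemset. Candidate k-itemsets are the
   classic level-wise join of lexicographically sorted (k−1)-itemsets sharing
   a (k−2)-prefix, pruned when any (k−1)-subset is infrequent. Mining S_w at
   m_min is provably equivalent to mining S_all at support threshold
   m_min·|S_w|/|S_all| and keeping the class-w rules (a tested invariant),
   but the search space scales with the rare class.
2. Confidence verification on S_all. For each candidate, l_w (matches in S_w)
   is counted first; the scan of S_¬w stops as soon as the running match
   count exceeds T_l = l_w·(1−c_min)/c_min, since confidence
   l_w/(l_w+l_¬w) < c_min iff l_¬w > T_l. The S_¬w scan follows the fixed
   load order, so the number of rows scanned before rejection is itself
   reproducible.

Counting uses a bitmap index: one boolean vector per item over the fixed row
order; itemset matching is a bitwise AND, counts are popcounts. Transactions
are produced by evaluating every vocabulary item's predicate on the raw
record; continuous features are first discretized into left-open/right-closed
intervals so emitted items print as "feature is >a and ≤b".

After mining, a specific rule is dropped when a strictly more general mined
rule with the same right-hand side has confidence not lower than the specific
rule's by more than τ; the dominating rule is recorded as a witness. The
retained count as a function of τ is non-increasing and flattens; the curve
(`rules_vs_tau_curve`) is emitted so τ can be re-derived on new data by
reading off where the asymptote starts.

The knowledge base contributes two declarative inputs: the set of items a
clinician marked as plausibly positively correlated with the poor outcome
(only those may appear in rules), and intervention texts linked to actionable
items. Both application points are supported — removing disallowed items from
transactions before mining (default, cheaper) or filtering finished rules —
and produce the same retained rule set on the same data.

At prediction time the top ⌈fraction·N⌉ instances by risk score are flagged
(ties at the boundary broken by ascending instance id, so the cutoff is
deterministic and permutation-invariant). Each flagged instance is explained
by every retained rule whose lhs it satisfies. Fitting rules are ordered
greedily: highest confidence first, thereafter the rule covering the most
not-yet-covered items (ties: higher confidence, smaller lhs, lexicographic
lhs); the first `top_n` are marked for default display. The published
description of this diversification defers to earlier work without restating
the algorithm, so this greedy maximum-new-coverage order is this package's
own deterministic formulation of the stated goal — that the top few displayed
rules be non-redundant.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| m_min | minimum commonality, fraction of S_w | 0.002 | data-dependent; raise until rules stay interpretable, lower until coverage suffices |
| c_min | minimum confidence | 0.5 | should far exceed the positive rate so users trust the rules |
| l_max | max lhs items | 5 | long rules are hard to read; 4 suits easier outcomes, 5 harder ones |
| τ | confidence-difference pruning threshold | 0.15 | re-derive from the rules-vs-τ curve per dataset |
| s_min | legacy support threshold on S_all | unset | balanced-data mode; converted internally to m_min·|S_all|/|S_w| |
| cutoff fraction | share of instances flagged | 0.1 | mirrors flagging the top decile of predicted risk |
| sample_fraction | instance subsample for mining | 1.0 | uniform without replacement, seeded |

Confidence ties at exactly c_min are kept (≥ comparison), and commonality
ties at exactly m_min likewise.

## Numerical choices

- The early-stop decision is evaluated in exact integer arithmetic: c_min is
  taken as a rational (numerator/denominator of the float) and the scan stops
  once the running count exceeds ⌊l_w(den−num)/num⌋. This makes the
  early-termination route bit-identical to a full count for any float c_min,
  with no epsilon.
- The commonality gate is likewise an integer threshold,
  count ≥ ⌈m_min·|S_w|⌉ with m_min treated exactly.
- The S_¬w scan is chunked (4096 rows) so vectorized counting and genuine
  early termination coexist; the reported rows-scanned is exact.
- Degenerate inputs: a constant continuous feature discretizes to a single
  bin and emits no interval items; missing numeric values satisfy no numeric
  item (a missing value never fires a risk item); an outcome with a single
  class yields zero information gain for every feature, with a warning;
  mining with zero instances of the interesting value is an error.
- Rounding in reports follows clinical-reporting convention: percentages to one
  decimal, means and sample SDs (n−1) to two decimals. Python's round
  (banker's) is used; at the printed precision of the tested quantities no
  half-way cases arise.

## Synthetic cohorts: what they emulate, and what they do not

`synthetic_cohort.generate_cohort` emulates an imbalanced patient-year cohort:
a 4% base positive rate (the poor outcome is rare), a handful of planted
conjunctive risk patterns, and independent noise items (inclusion probability
0.1) that carry no signal. Per instance, each planted left-hand side is
included jointly with its carrier probability; the outcome is drawn with the
target confidence of the highest-confidence planted rule the instance
satisfies, else at the base rate. The max-confidence semantics keeps planted
confidences identifiable when carriers overlap.

The default planted set (five rules, lhs sizes 1,1,2,2,3 over disjoint
asthma-flavoured items) uses one shared target confidence of 0.70 and carrier
fraction 0.12. Equal targets are deliberate: with independent carrier draws,
unequal targets would bias the empirical confidence of lower-confidence rules
upward wherever carriers overlap, making "estimated confidence vs target" an
ill-posed comparison; with equal targets the conditional positive rate of
each planted lhs is exactly its target. Carrier 0.12 yields roughly 2,400
carriers per rule at n = 20,000, so the binomial standard error of an
estimated confidence is ≈0.009 and a ±0.03 recovery band is ≈3 SE. This
benchmark cohort is consequently *not* rare-positive overall (~35% positive);
the `demo` profile (carrier 0.02, confidence 0.65) keeps the planted signal
sparse and the cohort strongly imbalanced (~10% positive) for end-to-end
coverage studies.

What passing these tests shows: the miner finds exactly the rules meeting the
gates, estimates their statistics exactly, and the pipeline explains the
flagged true positives wherever a planted pattern fires. What they do not
show: behaviour under correlated real-world features, drifting case mix,
many-valued categorical vocabularies, or miscalibrated external scores —
real cohorts have all of these, and coverage numbers on synthetic data do not
transfer.

## Design decisions

- Discretization defaults to equal-frequency binning (n_bins = 4 typical),
  with equal-width as the alternative; the downstream knowledge base controls
  which bins become rule items, so the binning algorithm is deliberately
  parameter-light and deterministic. Interval convention is left-open/
  right-closed throughout, including the one-sided ≤/≥ items.
- Witness eligibility in pruning: a specific rule is compared against all
  strictly-more-general *mined* rules, whether or not those are themselves
  dropped. Only existence is required, and this makes the retained set
  independent of processing order.
- Rules with an empty left-hand side are disallowed (n ≥ 1).
- Row order is fixed at load time and used for every sequential scan, making
  artifacts byte-reproducible under a fixed seed.
- The reference scorer is a regularized additive logistic model over item
  membership — a genuinely usable small risk model for demos; any external
  model's scores are ingested from CSV without retraining.
- Problem sizes in the shipped studies (20,000-instance cohorts, l_max = 3,
  ≤17 items) were chosen so every planted pattern is estimable with tight
  binomial error while a full study runs in seconds on one core.

## Known limitations

- Candidate generation is in-memory, pure-Python level-wise join; vocabulary
  sizes in the hundreds with l_max = 5 are fine, but very wide vocabularies
  would need candidate hashing or an FP-growth backend (out of scope).
- Interventions attach to items, not whole rules; rule-level intervention
  overrides are not implemented.
- Only one interesting outcome value is handled per pipeline run; multi-class
  outcomes are handled by iterating.
- The bitmap index is dense boolean; extremely sparse, very wide matrices
  would benefit from packed or sparse representations.
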