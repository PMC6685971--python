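"""Train the subgroup-ensemble screener on a synthetic cohort and
blind-test it.

Each anthropometric subset (BMI < 35, age groups, sex, neck
circumference, Mallampati) selects its own 3-/4-feature combination by
repeated random-forest out-of-bag validation; the subset votes
(+1 OSA x OOB sensitivity, -1 non-OSA x OOB specificity) are averaged
into the decision d in [-1, 1].

Note: this is the smallest meaningful demo; the full study-scale run is
`run_synthetic_study(seed=7)` (199 subjects, ~10 min on one CPU).
"""

import pandas as pd

from awakeosa import SyntheticSpec, evaluate, simulate_cohort
from awakeosa.pipeline import PipelineConfig, extract_features, train_screener
from awakeosa.reduction import ReductionConfig
from awakeosa.training import SubsetSpec

spec = SyntheticSpec(n_non_osa=24, n_osa=20, cycles=3)
records, signals = simulate_cohort(spec, seed=13)
config = PipelineConfig(
    n_trees=100, scoring_reps=2, final_reps=2, single_precision=True,
    bis_max_cycles=2, bis_excerpt_s=0.6, train_fraction=0.65,
    reduction=ReductionConfig(rounds=5, max_features=4),
    subsets=(SubsetSpec("bmi_lt_35", "bmi", "<", 35, include_nc=True),
             SubsetSpec("mps_le_2", "mps", "<=", 2, include_nc=True)),
)

table = extract_features(records, signals, config)
screener = train_screener(records, table, config, seed=13)

for m in screener.ensemble.models:
    print(f"subset {m.spec.name}: combination {m.combination}")
    print(f"  OOB sensitivity {m.oob_sensitivity:.2f} (weight of +1 votes), "
          f"specificity {m.oob_specificity:.2f} (weight of -1 votes)")

decisions = screener.screen(table)
test_ids = [r.subject_id for r in screener.split.test]
labels = pd.Series({r.subject_id: r.is_osa() for r in records})
metrics = evaluate(decisions.loc[test_ids], labels)
print(f"\nblind test ({metrics.n} subjects): accuracy {metrics.accuracy:.2f}, "
      f"sensitivity {metrics.sensitivity:.2f}, specificity {metrics.specificity:.2f}")
print(decisions.loc[test_ids[:5], ["d", "call", "high_confidence"]])
# d near +1/-1 means the subsets agree with strong validation weights;
# |d| > 0.7 flags high-confidence calls.
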