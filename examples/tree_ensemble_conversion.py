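"""Segment-wise random-forest conversion with participant-level splitting.

Each (beat, normalised time point) is one training row: 12 prone-lead
amplitudes + 6 covariates predict the standard-lead amplitude.  All of a
subject's cycles land on one side of the split, so the held-out score
measures generalisation to unseen people.
"""

from pronecg import (
    SegmentKind,
    SyntheticCohortConfig,
    cohort_feature_tables,
    feature_importance,
    participant_split,
    simulate_cohort,
    train_segment_models,
)
from pronecg.approach3 import FEATURE_NAMES
from pronecg.evaluation import regression_metrics

cohort = simulate_cohort(SyntheticCohortConfig(
    n_subjects=30, total_beats=250, noise_sd=0.0, seed=17))
tables = cohort_feature_tables(cohort, segments=(SegmentKind.QRS,))
train_ids, test_ids = participant_split(cohort.subject_ids(), 0.8, seed=17)
print(f"participant-level split: {len(train_ids)} train / {len(test_ids)} test")

bundle = train_segment_models(tables, "random_forest", {"ntree": 100},
                              seed=17, train_subjects=train_ids,
                              segments=(SegmentKind.QRS,))
df = tables[SegmentKind.QRS]
test = df[df.group.isin(test_ids)]
X = test[list(FEATURE_NAMES)].to_numpy()
print("\nheld-out QRS R^2 per target lead:")
for lead in ("V1", "V2", "V3", "V4", "V5"):
    pred = bundle.predict(lead, SegmentKind.QRS, X)
    r2 = regression_metrics(test[f"target_{lead}"].to_numpy(), pred).r2
    print(f"  {lead}: {r2:.3f}")

imp = feature_importance(bundle)
top = imp[(imp.lead == "V1") & (imp["rank"] < 3)]
print("\ntop features for the V1 QRS model:",
      ", ".join(top.feature.tolist()))
# prone V4 should dominate: the prone geometry places its electrode
# opposite the standard V1 site, the inverse pairing of the direct route.
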