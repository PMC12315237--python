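"""Turn one participant's visit history into a fixed-length L2C vector.

The transformation summarizes each biomarker's history relative to a chosen
forecast time tf: most recent value and its recency, recent change rate,
historical extremes, plus diagnosis-trajectory features and covariates —
always 70 named fields, however many visits were observed.
"""

from l2cforecast.features import assemble_features, augment_training_samples
from l2cforecast.simulate import SimConfig, generate_cohort

cohort = generate_cohort(SimConfig(n_participants=10, seed=4))
history = max(cohort, key=lambda h: h.n_visits)
tf = history.visits[-1].month + 12.0  # forecast one year past the last visit

vec = assemble_features(history, tf)
print(f"participant {history.participant_id}: {history.n_visits} visits, "
      f"forecasting at month {tf:.0f}")
print(f"feature vector has {len(vec)} named fields")
for name in ("mr_mmse", "time_since_mr_mmse", "mr_change_mmse",
             "low_mmse", "high_mmse", "mr_dx", "time_since_mr_dx",
             "milder", "time_since_milder", "age_at_tf",
             "months_since_baseline"):
    print(f"  {name:24s} = {vec[name]}")

samples = augment_training_samples(history)
m = history.n_visits
print(f"\naugmentation: {m} visits -> {len(samples)} training samples "
      f"(every prefix predicts every later visit; m(m-1)/2 = {m * (m - 1) // 2} "
      "before dropping target-less visits)")

# time_since_* fields are measured from tf in months; time_since_milder is
# 999 when no strictly milder diagnosis ever occurred (a semantic sentinel,
# not a missing value).
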