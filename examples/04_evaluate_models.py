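"""Compare model variants with the fold-level evaluation harness.

Runs a 3-fold cyclic cross-validation of the carry-forward baseline and the
single-model gradient-boosted variant on a simulated cohort, reports pooled
diagnosis mAUC and per-participant MMSE MAE per fold, and tests the
difference with the corrected resampled t-test.
"""

from l2cforecast.evaluate import compare_fold_metrics, run_experiment
from l2cforecast.simulate import SimConfig, generate_cohort

cohort = generate_cohort(SimConfig(n_participants=150, seed=2))

reports = {}
for variant in ("carry_forward", "xgb_nw"):
    reports[variant] = run_experiment(cohort, variant, k=3, seed=0,
                                      analyses=("main", "horizon"))
    main = reports[variant].query("analysis == 'main'")
    print(f"{variant}: mAUC per fold = "
          + ", ".join(f"{v:.3f}" for v in main["mauc"])
          + f"; MMSE MAE = {main['mmse_mae'].mean():.2f}")

test = compare_fold_metrics(reports["xgb_nw"], reports["carry_forward"],
                            "mauc", rho=1.0 / 2.0)  # test:train = 1:2 at k=3
print(f"\ncorrected resampled t-test on mAUC difference: "
      f"t = {test.statistic:.2f}, p = {test.p_value:.4f}")

horizon = reports["xgb_nw"].query("analysis == 'horizon'")
print("\nmAUC by forecast-horizon year (xgb_nw, averaged over folds):")
print(horizon.groupby("stratum")["mauc"].mean().round(3).to_string())

# A positive t with small p says the learned forecaster's pooled mAUC
# exceeds the carry-forward baseline beyond what overlapping training sets
# would explain; the horizon breakdown shows accuracy decaying as forecasts
# reach further into the future.
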