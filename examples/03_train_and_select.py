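"""Train the prediction suite and select the best model per nutrient.

Fits seven regressors (linear, LassoLars, random forest, gradient boosting,
AdaBoost stumps, RBF SVR, averaging ensemble) on an 80% split of the
measured training pools, tunes each by 5-fold grid search, and reports MAE /
RMSE / MAPE on the held-out 20%.  The random forest typically wins both
nutrients: the continuous donor covariates nearly identify donors, letting
deep trees learn each donor's consistent offset, which linear models cannot.
Takes a minute or two.
"""

from milkpool import (
    GeneratorParams, generate_cohort, form_single_donor_training_pools,
    train_suite, select_best, feature_importance,
)

cohort = generate_cohort(GeneratorParams(seed=0))
pools = form_single_donor_training_pools(cohort.bottles, cohort.donors, rng=0)

for nutrient, unit in (("protein", "g/100 mL"), ("energy", "kcal/100 mL")):
    models, report = train_suite(pools, nutrient, split_seed=0)
    best = select_best(report)
    print(f"\n=== {nutrient} ===")
    print(report.table.round(4).to_string())
    print(f"selected: {best} (test MAE "
          f"{report.table.loc[best, 'mae']:.3f} {unit})")
    if best == "random_forest":
        imp = feature_importance(models[best]).sort_values(ascending=False)
        print("feature importances:", ", ".join(f"{k}={v:.2f}" for k, v in imp.items()))
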