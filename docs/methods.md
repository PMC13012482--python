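# Methods

This note documents the models, assumptions, parameter choices and known
limitations of `milkpool`, stage by stage.

## Problem setting

A human milk bank receives individually expressed frozen donations
(bottles of roughly 50–250 mL) and combines them into ~2-litre pools before
pasteurisation. Pool composition is measured once on a mid-infrared human
milk analyser; individual bottles are never measured. The bank wants every
pool near 1.0 g crude protein and 70 kcal per 100 mL. Crude protein is true
protein (from total nitrogen) inflated by ~20% for non-protein nitrogen;
energy follows from Atwater factors (4/9/4 kcal per g of protein, fat,
carbohydrate — the factors are configurable since conventions differ
slightly). Bottles are stored at −20 °C for at most 3 months, operationalised
as 91 days.

## Synthetic cohort generator

The real milk-bank database is proprietary, so every stage runs on a
synthetic cohort built to the same scale: 480 donors whose donations form
roughly 2.2k single-donor training pools. Bottle-level crude protein and
energy are each the sum of

1. **fixed covariate effects** — linear in days postpartum, donor BMI, age,
   preterm delivery, vegetarian diet, and (for energy) expressed volume,
   centred at cohort means;
2. **correlated donor random intercepts** (SD 0.15 g and 6.0 kcal per
   100 mL, correlation 0.36) — the within-donor consistency that makes
   single-donor pools nutritionally variable *between* donors, which is the
   entire case for multi-donor pooling; and
3. **bottle-level residual noise** (SD 0.25 g, 9.3 kcal), plus analyser
   measurement noise (SD 0.10 g protein, 1.5 kcal energy) added once per
   measured pool.

Effect sizes were calibrated analytically (`β_i = r_i σ_pool / σ_covariate`)
and checked empirically so that, at ~2.2k pools, the pool-level Pearson
correlations land within ±0.05 of the target table (protein: days
postpartum −0.20, BMI −0.10, age −0.10, preterm +0.06, vegetarian +0.05,
volume ≈ 0; energy: days postpartum +0.17, volume −0.15, BMI +0.05,
age +0.17; protein–energy cross +0.16), then frozen as defaults. In
moderate cohorts a chance alignment between donor intercepts and donor
covariates would confound this structure (sampling error ~ n_donors^−1/2),
so the intercepts are projected off the donor-level design and rescaled;
this is skipped below 30 donors, where the projection would absorb the
intercepts themselves.

Donor covariates (age ~ N(32, 4²) on [18, 45]; BMI ~ N(24, 3.5²) on
[17, 40]; 12% vegetarian; 25% preterm) are plausibility choices at the
reported cohort shares, not measured distributions. Donation timelines are
daily expression inside a window of lactation (start uniform on 30–240 days
postpartum, length 11–30 days) with 2–4 bottles per day — several bottles a
day is what makes a 2-litre single-donor pool of ≤250 mL bottles reachable
within the 7-day adjacency limit that training pools respect. Fat is derived
from energy, protein and carbohydrate (carbohydrate ~ N(7.0, 0.25²)) so the
Atwater identity holds exactly; floors (protein ≥ 0.4 g, energy ≥ 45 kcal,
fat ≥ 0.5 g per 100 mL) guard against unphysical Gaussian tails.

What the generator does **not** emulate: fore/hind-milk and diurnal fat
variation, nonlinear lactation trajectories, seasonal effects, missing or
erroneous records, and donor drop-out. Passing tests therefore show the
pipeline is correct and effective *under this data-generating process*, not
that the same effect sizes hold at any particular bank.

## Exploratory statistics

Pearson correlations (two-sided t-test p-values, point-biserial for the 0/1
covariates) and per-nutrient OLS with all six covariates jointly. No
multiple-testing correction — the stage is exploratory, and the 0.05
threshold is reported but never acted on. p-values below 0.001 are formatted
as "<0.001" in display output while exact values are retained.

## Prediction

Models are trained on pool-level rows (pool-averaged days postpartum and
volume per expression joined with donor covariates) because only pools are
measured; bottle-level predictions then substitute the bottle's own days
postpartum and volume for the pool averages. That pool-to-bottle transfer is
an approximation, which is exactly why a per-nutrient MAE bound feeds the
robustness analysis.

The suite: ordinary linear regression, LassoLars, random forest, gradient
boosting, AdaBoost on stumps, RBF-kernel SVR on standardised inputs, and an
unweighted averaging ensemble. Each is tuned by 5-fold cross-validated grid
search on a random 80% split (grids kept ≤ 24 combinations per learner so a
full run stays at desk scale; see `predict.CVConfig`), and metrics (MAE,
RMSE, MAPE, plus the SD of the fold scores at the chosen hyperparameters)
come from the held-out 20%. Selection is by held-out MAE with RMSE and then
model name breaking ties. The random forest wins both nutrients on the
default cohort: the continuous covariates (age, BMI, donor mean volume) are
nearly donor-identifying, so deep trees recover each donor's consistent
offset for donors present in training — the mechanism behind pool-level
MAEs near the analyser's own measurement error — while linear models see
only the weak population-level covariate signal. For donors never seen in
training, predictions fall back to that covariate signal. Bottle predictions
are clipped to physical floors (0.3 g, 40 kcal per 100 mL).

## Pooling MILP

Formulation, linearisation and the ε-lexicographic expiry term are
documented in `milkpool/optimise.py`. Numerical choices:

* **Normalisation.** Deviations are dimensionless (relative to target), so
  protein (~1 g) and energy (~70 kcal) are commensurate. The objective
  divides by the *fixed* reference volume `V_ref = 2000 mL` to stay linear;
  since realised pool volume is within [2000, 2050], this understates the
  exact normalised deviation by at most 2.5%, and `evaluate_assignment`
  always recomputes the exact per-pool `|c − T|/T` post hoc. Reported
  assignments carry both numbers (`objective_total` exact,
  `linear_objective` as the solver saw it).
* **Expiry priority** is an objective reward (weight 10⁻⁴ on urgency
  `1 − days-to-expiry/91`, clipped to [0, 1]) rather than a hard FIFO
  constraint, which could destroy feasibility. At this weight it cannot
  trade deviation for urgency on any instance whose deviation optima are
  separated by more than ~10⁻³; it only breaks ties.
* **Symmetry.** Pools are interchangeable, so the model fixes
  `x_bp = 0` for `p > b` — valid because pools can be relabelled by their
  minimal member bottle index — which removes most of the symmetric search
  tree.
* **Solver settings.** HiGHS via `scipy.optimize.milp`; default relative
  gap 10⁻⁶ and 300 s limit, overridable everywhere. Solutions are never
  trusted: an independent audit re-checks single assignment, volume and
  donor windows before evaluation, and the test suite checks the optimum
  against exhaustive enumeration on ≥ 20 small instances.
* **Degenerate inputs.** Missing predictions fail fast;
  `n_pools · vmin` exceeding available volume warns before solving;
  infeasibility is diagnosed by re-solving with donor bounds relaxed
  (feasible ⇒ "donor-count", else "volume").
* Unassigned-but-available bottles incur no penalty; `suggest_n_pools`
  proposes `⌊total volume / vmax⌋`.

## Robustness and sensitivity

Predictions are uncertain, so each bottle's composition is modelled as an
interval of half-width equal to the selected model's per-nutrient MAE
(defaults 0.112 g, 5.34 kcal per 100 mL) around the prediction. For a fixed
assignment the worst case is closed-form: pool mass deviation is linear in
bottle contents, so its maximum over the box is the nominal deviation plus
the pooled half-width `Σ_b (v_b/100) e_n`, attained when every content
shifts away from the target. Half-widths are per-bottle (the MAE is a
bottle-prediction error), so pool-level uncertainty is volume-weighted; the
two nutrients are treated independently. The headline mode fixes the
nominal-optimal assignment and maximises (fix-then-maximise); min-max
robust *re-optimisation* is available by passing the uncertainty set to
`build_model` — the worst-case objective is itself linear in `x`, so the
robust counterpart stays a MILP.

Sweeps re-solve scenarios over pool counts 2–15 (infeasible counts flagged,
not fatal) and over (min, max) donor-bound combinations, reporting the
per-pool normalised objective and realised donors per pool. Monotonicity
(wider donor bounds never worsen the optimum) holds for the solver's own
objective and is asserted on exactly solved instances.

## Baseline and rolling horizon

Current practice is greedy single-donor pooling: per donor, bottles in
expression order accumulate and the pool closes at the first bottle
reaching 2.00 L, so a pool may slightly exceed 2.05 L when the closing
bottle is large — the loose way pooling is done in practice; a stricter
`skip_overshoot` variant is available. Pooling cadence defaults to weekly
(banks do not publish their cadence). At each date a strategy sees only
arrived, unexpired, unconsumed bottles; the optimised strategy builds
`⌊available volume / vmax⌋` pools, backing off one pool at a time if
infeasible. Both arms are scored on **true** synthetic compositions — the
comparison measures realised stability, not predicted stability — and on
waste (volume expiring unconsumed) and mean remaining shelf life (earliest
member expiry minus pooling date; multi-donor pools are expected to have
shorter shelf lives, the known cost of the strategy).

## Problem sizes used in tests and the acceptance script

Chosen as the package's own desk-scale defaults: the full 480-donor cohort
(~2.2k pools) for correlation recovery and model training; a compact fresh
8-donor cohort (~200 bottles, ~36 L, 15 weekly pooling dates, per-solve
limits 15 s at gap 5·10⁻³) for the rolling-horizon comparison, with models
trained on the full cohort; 24-bottle/8-donor inventories for sensitivity
sweeps (donor-bound sweeps solved to gap 10⁻⁶); and ≤ 12-bottle instances
for oracle verification. Scenario MILPs accept time-limited incumbents;
verification and monotonicity checks only ever use exact solves.

## Known limitations

* Training pools and bottle predictions share the feature-averaging
  approximation; no uncertainty beyond the scalar MAE bound is modelled.
* The generator's effect sizes are calibrated to one correlation table;
  other banks' cohorts will differ, and absolute deviations reported on
  synthetic data do not transfer.
* The MILP is single-period per pooling date; no look-ahead across dates.
* Bottle splitting, demand modelling, pasteurisation losses and costs are
  out of scope.
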