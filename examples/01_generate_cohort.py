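"""Generate a synthetic donor cohort and inspect its structure.

Builds the default cohort (~480 donors, ~32k frozen bottles, ~2.1k measured
single-donor training pools) and prints its headline shape plus the mean
composition.  The printed means should sit near the bank's targets of
1.0 g crude protein and 70 kcal per 100 mL, with pool-to-pool SDs of roughly
0.2 g and 7 kcal — the donor-to-donor variability the pooling strategy is
meant to tame.
"""

from milkpool import GeneratorParams, generate_cohort, form_single_donor_training_pools

cohort = generate_cohort(GeneratorParams(seed=0))
pools = form_single_donor_training_pools(cohort.bottles, cohort.donors, rng=0)

print(f"donors:          {len(cohort.donors)}")
print(f"bottles:         {len(cohort.bottles)}")
print(f"training pools:  {len(pools)}")
print(f"bottle volume:   {min(b.volume_ml for b in cohort.bottles):.0f}"
      f"-{max(b.volume_ml for b in cohort.bottles):.0f} mL")
print(f"pool crude protein: {pools.crude_protein.mean():.3f} "
      f"+/- {pools.crude_protein.std():.3f} g/100 mL")
print(f"pool energy:        {pools.energy.mean():.2f} "
      f"+/- {pools.energy.std():.2f} kcal/100 mL")
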