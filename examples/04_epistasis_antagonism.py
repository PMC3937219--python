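"""Fitness antagonism relative to the multiplicative null.

Combination fitness falls short of the product of single-mutant
fitnesses (epsilon < 0), and the most beneficial singles are the most
antagonistic in combination — the s vs epsilon trend.
"""

import fitscape as fs
from fitscape.epistasis import records_from_strain_table

study = fs.generate_study(fs.default_design(), fs.default_effects(),
                          fs.default_true_params(), fs.NoiseModel(seed=3))

r2, adj_r2, resid = fs.fit_multiplicative_fitness_null(study)
print(f"multiplicative null on 12 combinations: R^2 = {r2:.2f}, "
      f"adj R^2 = {adj_r2:.2f}")
print(resid.round(3).to_string(index=False))

records = records_from_strain_table(study)
trend = fs.s_epsilon_trend(records, compare=("A3", "B5"))
print("\nper-mutation mean epsilon over backgrounds:")
print(trend.per_mutation.round(3).to_string(index=False))
print(f"\nOLS slope of mean epsilon on s: {trend.slope:.2f} "
      f"(95% CI {trend.slope_ci[0]:.2f}..{trend.slope_ci[1]:.2f})")
print(f"Welch t-test A3 vs B5 epsilon sets: p = {trend.t_pvalue:.3f}")
print(f"sign epistasis observed in {int(records['sign_epistasis'].sum())} "
      f"of {len(records)} records")
print("negative slope: the individually best mutations interact worst")
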