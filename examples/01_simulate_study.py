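"""Generate a synthetic study with known ground truth.

Builds the default design — one ancestor, three Class A mutants
(lower per-copy expression), four Class B variants (lower plasmid copy
number), all 12 A x B combinations and a 12-level inducible-promoter
dilution series — and prints the strain table.  Observed phenotypes
are triplicate-averaged noisy measurements; the *_true columns carry
the noise-free ground truth the estimators are later judged against.
"""

import fitscape as fs

study = fs.generate_study(fs.default_design(), fs.default_effects(),
                          fs.default_true_params(), fs.NoiseModel(seed=1))

print(study[["strain", "genotype", "category", "partition",
             "flha_obs", "fgha_obs", "copy_obs", "fitness_obs"]]
      .round(3).to_string(index=False))
print(f"\n{len(study)} records: the 'fit' partition (ancestor, singles, "
      "inducible series) trains the landscape model; the 12 'predict' "
      "combinations are held out for out-of-sample scoring.")
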