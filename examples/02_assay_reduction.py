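"""Reduce raw assay observations to phenotypes.

Simulates a head-to-head competition (64-fold expansion, binomially
sampled flow-cytometry counts) and a qPCR copy-number determination,
then inverts both with the reduction functions.
"""

import fitscape as fs
from fitscape.synthetic import GENOME_COPIES_PER_25NG

# competition: a mutant with true relative fitness 1.45
assay = fs.simulate_competition_counts(w_true=1.45, expansion=64,
                                       n0=100_000, n1=100_000, seed=4)
w = fs.competition_fitness(assay)
print(f"initial test fraction f0 = {assay.f0:.4f}, final f1 = {assay.f1:.4f}")
print(f"recovered W = {w:.4f} (truth 1.45; s = {fs.selection_coefficient(w):+.4f})")
print(f"a 1/64 serial transfer is {fs.generations_per_cycle(64):.0f} "
      "generations per cycle\n")

# qPCR: ancestral plasmid at ~9 copies per genome
dct, standards = fs.simulate_qpcr(9.0, noise=fs.NoiseModel(qpcr_sd_ct=0.05,
                                                           seed=4))
curve = fs.fit_standard_curve(list(zip(standards["dct"],
                                       standards["molecules"])))
copies = fs.copies_per_genome(dct, curve, GENOME_COPIES_PER_25NG)
print("standard curve: slope per log2(molecules) = "
      f"{curve.slope:.3f}, R^2 = {curve.r_squared:.4f}")
print(f"sample dCt = {dct:.2f} -> {copies:.2f} plasmid copies per genome "
      "(truth 9)")
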