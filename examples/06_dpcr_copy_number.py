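"""Plasmid copy number per genome from digital PCR.

A chip partitions the sample into ~20 000 chambers; Poisson correction
(lambda = -ln(1 - positive fraction)) converts each channel's positive
count into a concentration, and the plasmid/genome ratio of the two
channels is the copy number.  The 95% interval is a binomial bootstrap.
"""

import numpy as np

from oricompat import copy_number, gen_dpcr_chip

true_ratio = 20.0  # plasmids per genome
rng = np.random.default_rng(3)
chip = gen_dpcr_chip(true_ratio, lambda_genome=0.05, n_partitions=20_000, rng=rng)
print(f"chip: {chip.positives_plasmid} FAM+ / {chip.positives_genome} HEX+ "
      f"of {chip.n_partitions} partitions")

est = copy_number(chip, bootstrap_reps=10_000, rng=rng)
print(f"copy number estimate: {est.point:.2f} "
      f"(95% CI {est.ci_low:.2f}-{est.ci_high:.2f}; truth {true_ratio})")
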