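"""Censusing a variant library from sequencing reads, and the loop-length
copy-number law.

Reads are quality-trimmed from the 3' end (10-base window, mean > 20),
filtered for the four constant flank motifs in order, and the inter-flank
variant region is deduplicated and counted.  Separately, a synthetic
origin panel shows the inverse linear relation between summed hairpin
loop length and plasmid copy number.
"""

from oricompat import count_variants, fit_copy_number_vs_loop, top_k_fraction
from oricompat.synthetic import gen_origin_set, gen_reads, variant_region

mixture = [
    (variant_region(["ACGTACG", "TTGACAA", "GGCATGC"]), 0.6),
    (variant_region(["CCCTACG", "TTGACAA", "GGCATGC"]), 0.3),
    (variant_region(["ACGTACG", "AAAACAA", "GGCATGC"]), 0.1),
]
reads = gen_reads(mixture, n_reads=1000, error_rate=0.0, seed=5,
                  low_quality_tail=12)
table = count_variants(reads)
print(table[["count", "frequency"]].to_string(index=False))
print(f"top-2 share of the sample: {top_k_fraction(table, 2):.0%}")

variants = gen_origin_set(24, seed=2, noise_sd=4.0)
fit = fit_copy_number_vs_loop(variants)
print(f"\ncopy number vs summed loop length: slope {fit.slope:.2f} "
      f"copies/nt, R^2 = {fit.r_squared:.4f}")
# Longer RNAI loops -> more effective antisense inhibition -> fewer
# plasmids: a sequence-level dial for copy number.
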