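"""Haplotype diversity, mean pairwise differences and intra-population
variance for one simulated Y-chromosome lineage.

Simulates 70 chromosomes descending from a single founder 7,000 years ago
(star genealogy, stepwise mutation at the evolutionary rate) and prints the
Y-STR summary statistics a population study would report for the lineage.
"""
import numpy as np

from ylineage import (
    STRHaplotype,
    count_distinct_haplotypes,
    haplotype_diversity,
    intra_population_variance,
    mean_pairwise_difference,
    mutate_str,
    simulate_genealogy,
)

LOCI = [f"DYS{i}" for i in range(1, 16)]  # a generic 15-locus panel
founder = STRHaplotype({l: 13 for l in LOCI})

genealogy = simulate_genealogy(70, "star", age_years=7000, gen_years=25, seed=42)
haps = mutate_str(genealogy, {l: 6.9e-4 for l in LOCI}, founder, seed=42)

div = haplotype_diversity([h.vector(LOCI) for h in haps])
mpd = mean_pairwise_difference(haps, LOCI)
vp = intra_population_variance(haps, LOCI)

print(f"N = {div.n}, distinct haplotypes h = {count_distinct_haplotypes(haps, LOCI)}")
print(f"haplotype diversity = {div.value:.3f} +/- {div.se:.3f}")
print(f"mean pairwise difference = {mpd.mean:.2f} +/- {mpd.sd:.2f} loci")
print(f"intra-population variance Vp = {vp.value:.2f} repeat^2")

# Diversity is the (unbiased) chance two random chromosomes differ; MPD counts
# at how many of the 15 loci they differ on average; Vp averages the per-locus
# allele-size variance — the raw material of the R_ST distance.
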