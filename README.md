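# ylineage

Population genetics of the human Y chromosome from combined Y-SNP and Y-STR
typing, built for studies of admixed and founder populations — the motivating
use case is the male population of Greenland, a mixture of Inuit lineages
within haplogroup Q-M242 and European lineages (I-M170, R1a-M513, R1b-M343),
analysed region by region. The library covers the full analysis chain:

- **Haplogroup assignment** against a rooted Y-SNP marker tree, with the
  field's paragroup nomenclature (`Q-NWT01 (xM265)`, `Q*-M242`): a chromosome
  is placed at the deepest node whose defining marker is derived, untyped
  markers are unknown (not ancestral), and the typed-ancestral downstream
  markers are listed as exclusions.
- **Diversity statistics** — Nei's unbiased haplotype/haplogroup diversity
  *H* = *n*/(*n*−1)(1 − Σ*p*ᵢ²), mean pairwise differences (MPD) with
  Tajima's total variance, intra-population allele-size variance *V*ₚ, and
  Fisher's exact 2×2 test.
- **Pairwise genetic distances** — single-level AMOVA Φ statistics:
  *F*<sub>ST</sub> on haplogroup identity and Slatkin's *R*<sub>ST</sub> on
  squared repeat-count differences, with permutation p-values
  (*k*+1)/(*B*+1); model-based distances from discrete Laplace (two-sided
  geometric) mixtures fitted by EM; classical (Torgerson) MDS embeddings.
- **Median-joining networks** of Y-STR haplotypes under the weighted stepwise
  distance *d*(*x*,*y*) = Σ<sub>ℓ</sub> *w*<sub>ℓ</sub>|*x*<sub>ℓ</sub> −
  *y*<sub>ℓ</sub>|, with inverse-variance locus weights 1–5, founder
  selection, and the ρ statistic: ρ = mean mutational steps from the sampled
  chromosomes to the founder, σ² = Σ<sub>branches</sub> *n*ᵦ²/*n*².
- **TMRCA dating** — *T* = ρ·*g*/(*L*·μ) years, default μ = 6.9×10⁻⁴ per
  locus per generation (the "evolutionary" Y-STR rate) and *g* = 25 years.
- **A synthetic-data generator** (star or conditioned Kingman coalescent
  genealogies, stepwise mutation, tree-consistent SNP states, region-level
  lineage mixtures) so every stage is testable with known truth and no
  external data.

The 17-locus Yfiler panel is pre-configured: statistics run on the 15-locus
analysis subset (DYS385a/b excluded because the order of its two alleles is
undeterminable; DYS389b = DYS389II − DYS389I replaces DYS389II).

## Worked example

Dating a simulated lineage of 70 chromosomes whose founder lived 7,000 years
ago (`examples/04_network_and_tmrca.py`):

```text
network: 70 nodes (4 inferred medians), 84 edges
rho = 3.70 +/- 0.95 mutational steps -> TMRCA = 8,937 +/- 2,288 years
rho 1.81 -> 4,372 years
```

The network links the observed haplotypes (plus four inferred median
vectors) by single-repeat steps; ρ averages the step distance from each
chromosome to the selected founder node, and the conversion divides by the
panel-wide mutation rate (15 × 6.9×10⁻⁴ mutations per generation ≈ one
mutation per 2,415 years). The last line is the purely arithmetic
conversion: a ρ of 1.81 on this panel corresponds to ≈ 4,400 years.

The other scripts under `examples/` each exercise one capability
(assignment, diversity summaries, distances + MDS, the full pipeline); the
`ylineage` console command exposes the same pipeline from the shell
(`ylineage simulate`, `assign`, `stats`, `dist`, `mds`, `network`, `tmrca`,
`all`).

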