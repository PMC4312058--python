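# Methods

This note records the statistical conventions, default parameters and design
choices implemented in `ylineage`, and what the synthetic-data tests do and
do not demonstrate about real data.

## Data model and pre-processing

A sample is one male chromosome: a Y-SNP genotype (each marker ancestral /
derived / missing) and a Y-STR haplotype (locus → repeat count, stored as
exact rationals so microvariants such as 17.2 are representable). The
default panel is the 17-locus Yfiler kit; haplotype-level statistics use the
15-locus analysis subset:

* **DYS385a/b is excluded** — the kit reports the two alleles of this
  duplicated locus without physical order, so per-copy identity across
  samples is undefined.
* **DYS389b = DYS389II − DYS389I** replaces DYS389II: the DYS389II amplicon
  contains the DYS389I stretch, and the subtraction makes the two analysis
  loci independent. DYS389II < DYS389I is rejected as impossible; a zero
  difference is stored but logged as suspicious.
* A sample with a **duplicated allele** at any analysis locus (e.g. a
  GATA H4 duplication) is excluded entirely; a sample **missing** an
  analysis-locus allele is excluded from haplotype-level statistics only and
  retained for haplogroup counts. The second rule is the package's own
  choice — network and ρ methods need complete haplotypes, while SNP-based
  counting does not — and the exclusion log records both kinds.

Stepwise distance between alleles is |x−y| rounded to the nearest integer;
a non-integer difference (microvariant against full repeat) warns, because
single-repeat mutation cannot interconvert them.

## Haplogroup assignment and nomenclature

The marker tree is a YAML config (one node per haplogroup: parent +
defining markers). Assignment returns the deepest node whose marker is
derived, requiring all derived nodes to lie on a single root path and no
root-path marker to be typed ancestral (either situation is reported as a
genotype inconsistency naming the markers). Untyped markers are *unknown*:
hierarchical typing strategies deliberately leave most of the tree untyped,
so absence of typing never counts as ancestral.

Paragroup labels list the typed-ancestral children: `Q-NWT01 (xM265)`.
Star labels (`Q*-M242`) are used when every typed child is ancestral *and*
the node is flagged `star_form` in the config — the flag exists because the
field writes some paragroups with a star and others with an exclusion list,
a purely conventional distinction that cannot be derived from tree state.
Haplogroup frequencies are plain counts; percentages are presentation only.

## Diversity statistics

* **Haplotype/haplogroup diversity**: Nei's unbiased estimator
  H = n/(n−1)(1 − Σp²), standard error from Nei's sampling variance
  2/(n(n−1))·[2(n−2)(Σp³ − (Σp²)²) + Σp² − (Σp²)²]. H = 1 exactly when all
  n types are distinct.
* **MPD**: mean number of analysis loci at which two haplotypes differ over
  all n(n−1)/2 pairs (identity convention, not allele-size distance — the
  squared-size convention is reserved for R_ST). The ± term is Tajima's
  total variance (sampling + coalescent stochasticity),
  V = (3n(n+1)π + 2(n²+n+3)π²)/(11(n²−7n+6)); its denominator vanishes at
  n ≤ 6, where the per-term form (n+1)/(3(n−1))·π + 2(n²+n+3)/(9n(n−1))·π²
  is used. The ± term is a scale indicator and is property-tested only.
* **Vp**: across-loci mean of the per-locus sample variance (n−1 divisor) of
  repeat counts; translation-invariant, zero iff all haplotypes identical.
* **Fisher's exact test**: two-sided by hypergeometric enumeration (via
  scipy); a zero margin returns p = 1 by convention. The test suite checks
  it against a brute-force enumeration oracle for all small tables.

## AMOVA distances and permutation tests

F_ST and R_ST are the single-level AMOVA ratio Φ = σ²ₐ/(σ²ₐ+σ²ᵥ) computed
from squared inter-individual distances — 0/1 haplogroup identity for F_ST,
Σℓ(xℓ−yℓ)² for R_ST (Slatkin's convention). Negative point estimates are
reported as computed (they are clamped to zero only when a matrix is fed to
MDS). Permutation p-values reassign individuals between the two populations
uniformly at random; p = (k+1)/(B+1) with B = 10,000 by default, which never
returns 0. Because group sizes are fixed under permutation, Φ is a monotone
decreasing function of the within-group sum of squares, and the loop
compares that sum directly — a computational shortcut with identical p.

## Discrete Laplace model

A population's haplotype distribution is modelled as a mixture over clusters
of per-locus discrete Laplace pmfs f(x; p, y) = (1−p)/(1+p)·p^|x−y|. Fitting
is EM with k-medoids initialisation on the stepwise distance; the M-step is
exact per coordinate (weighted median for the central haplotype, closed-form
dispersion MLE p = (√(1+m²)−1)/m from the weighted mean absolute deviation
m), so the log-likelihood is non-decreasing. Dispersions are clipped to
[10⁻⁶, 1−10⁻⁶]; an empty cluster is re-seeded once.

The between-population distance is a Bhattacharyya affinity distance on the
fitted models, d = 1 − A₁₂/√(A₁₁A₂₂), with A computed exactly by per-locus
geometric series over cluster pairs. The √(A₁₁A₂₂) normalisation makes
d(m, m) = 0 hold exactly for multi-cluster mixtures (the raw cluster-pair
sum exceeds 1 there) and reduces to the plain Bhattacharyya distance for the
default one-cluster-per-population fit. Published model-based distances from
other implementations may use a different between-population functional, so
these distances are property-tested (symmetry, zero self-distance,
closed-form vs truncated-sum agreement) rather than compared to printed
tables.

## Classical MDS

Torgerson scaling: clamp negative input distances to 0, double-centre the
squared distances, eigendecompose, take the top-k coordinates. If fewer than
k positive eigenvalues exist the remaining coordinates are zero with a
warning. Euclidean-embeddable inputs are reproduced to numerical precision
(tested at 10⁻⁹).

## Median-joining networks, ρ and TMRCA

Connection cost uses the weighted stepwise distance with integer locus
weights 1–5 from inverse allele-size variance. The weights are assigned by
rank: loci are ranked by inverse variance (average ranks on ties) and the
ranks mapped to five equal quantile bins, weight ⌈5·rank/L⌉ — most variable
locus 1, least variable 5, invariant loci 5. (Equal-width binning of the raw
inverse variances was rejected: it collapses under the heavy right skew of
1/variance and cannot reproduce the intended 5…1 laddering of evenly
log-spaced variances.)

Construction: (1) ε-relaxed minimum-spanning network — an edge is kept iff
its length is within ε of the Kruskal merge threshold of its endpoints
(ε = 0 by default, the reference tool's default); (2) for each mutually
connected triple, the per-locus median vector is a candidate; the candidate
whose addition most reduces the minimum-spanning cost is added, and the step
repeats to a fixpoint (lexicographic tie-breaks make the result independent
of input order); (3) median vectors of degree < 3 are pruned. All observed
haplotypes remain nodes and the minimum spanning tree over the final node
set is always contained in the network.

The founder is by default the modal observed haplotype (ties: maximal
network degree, then lexicographic order), overridable by an explicit
haplotype. ρ is the sample-weighted mean of *unweighted* mutational steps
along shortest network paths to the founder — weights guide topology, not
mutation counting. σ² = Σ over shortest-path-tree branches of
(steps)·(descendant chromosomes)²/n²; for a pure star this collapses to
σ² = ρ/n. Without a network (e.g. mass simulation), ρ and σ use direct
stepwise distances with shared-haplotype grouping, which equals the network
quantity whenever the network is a homoplasy-free tree.

TMRCA: T = ρ·g/(L·μ) years with μ = 6.9×10⁻⁴ mutations per locus per
generation (the evolutionary rate calibrated on population divergences;
pedigree rates are ~3× higher and are appropriate for genealogical, not
population, time scales) and g = 25 years — on 15 loci, one mutation per
≈ 2,415 years. The standard error scales identically from σ. All three
constants are arguments.

## Synthetic data

The generator emulates exactly the structure the estimators assume: one
genealogy per lineage (star, or a Kingman coalescent rescaled so the
realized root age equals the requested founder age — the rescaling *is* the
conditioning that makes the root the founder), Poisson(μ·branch length)
stepwise mutations per locus (each ±1 with equal probability, repeat counts
floored at 1), SNP states derived exactly on the lineage's root path, and
per-region multinomial draws over lineages. Identical scenario + seed gives
byte-identical output files. The default scenario reproduces the regional
mixture of a five-region arctic cohort (N = 68/24/64/27/44) with two Inuit
lineages (founder ages 7,038 and 4,366 years — ρ-based point estimates for
such lineages), three European lineages (12,000–15,000 years) and a rare
'other' lineage; the default mutation rate equals the estimation default so
that simulation and dating calibrations cancel.

What the simulator does **not** emulate: locus-specific mutation rates (one
rate for all loci by default, though per-locus rates are accepted),
multi-step mutations, typing error and allelic dropout, population growth or
migration between regions after founding, and the haplotype-sharing excess
that real genealogies produce relative to a star. Consequently simulated
cohorts are *more* haplotype-diverse than real ones of the same age (the
default cohort's lineages show diversity ≈ 0.95–1.0 where a real cohort
shows 0.86–0.90), and passing tests demonstrate estimator correctness under
the model, not that real data meet the model.

Known calibration limit: ρ counts *net* observed steps, so back-mutations
make it underestimate age — per locus the expected displacement is
λe^{-λ}(I₀(λ)+I₁(λ)) for λ = μT/g mutations, ≈ λ(1−λ/2) when λ is small.
At the evolutionary rate this bias is ≈ 2.5% at 2,000 years, ≈ 9% at 7,000
years, and grows beyond 10% past ≈ 8,000 years; the parameter-recovery tests
therefore run at the cohort-relevant ages (within 10% there), and deep-time
dating should be read with this compression in mind.

## Numerical and degenerate-input conventions

* Diversity/MPD/Vp require n ≥ 2; MPD requires complete haplotypes.
* Permutation p-values are never 0 (add-one rule); n_perm = 0 skips testing.
* Zero-variance loci get weight 5; identical haplotypes give a zero-variance
  discrete Laplace fit with dispersions at the lower bound.
* Negative Φ estimates are preserved in tables, clamped to 0 for MDS input.
* Network tie-breaks (median candidates, founder selection) are
  lexicographic on haplotype vectors; shuffling the input yields an
  isomorphic (identically labelled) graph.
* All stochastic APIs accept either an integer seed or a numpy Generator.
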