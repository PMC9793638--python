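# Methods

## Model

`inbredsim` simulates a diploid, monoecious, randomly mating population with
discrete generations, forward in time, under an infinite-sites model.

**Genome.** The default genome is pig-like: 18 chromosomes of 125 Mb,
recombination rate 8×10⁻⁹ per bp per meiosis (≈1 crossover/chromosome,
0.8 cM/Mb) and mutation rate 4×10⁻⁹ per bp per gamete. Crossover counts are
Poisson per chromosome without interference, positions uniform; chromosomes
assort independently. Positions are integer bp on 1-based closed coordinates;
crossover points fall between bp. Three mutation-model presets are exposed:
`default` (5% of mutations deleterious, s̄ = 0.1), `high_density` (μ = 9×10⁻⁹
with 2.22% deleterious, i.e. the same deleterious genomic rate), and
`alternative` (10% deleterious at the default μ — double the deleterious
genomic rate — with s̄ = 0.025).

**Mutation effects.** A new mutation is deleterious with the preset's
probability; otherwise neutral (s = 0). Deleterious mutations draw
s ~ Exponential(s̄) capped at 1 (the cap affects <0.005% of draws at
s̄ = 0.1) and h | s ~ Uniform(0, e^(−ks)), so more damaging mutations are more
recessive. Since E[h] = E[e^(−ks)]/2 = 1/(2(1 + k s̄)), the decay constant has
the closed form k = (1/(2h̄) − 1)/s̄, i.e. k = 15 for (s̄, h̄) = (0.1, 0.2)
and k = 60 for (0.025, 0.2); h̄ > 0.5 is rejected as infeasible.

**Fitness and selection.** Genotype fitness is multiplicative across loci
with factors 1, 1 − sh, 1 − s. Natural selection enters reproduction as
fitness-proportional sampling of parents: each parental slot of each
offspring is drawn with probability ∝ w, the two parents of an offspring are
forced distinct (no selfing), and polygamy is free. This is a design choice —
how fitness enters reproduction is not dictated by the model statement — and
it produces the expected purging of strongly deleterious alleles in small
lines (a property test asserts the decline of s > 0.2 allele frequencies
under selection). Fitness used for selection and reported per individual is
relative to the best genotype at *segregating* loci; deleterious sites fixed
in the whole population (or in a line's founders) contribute a constant
factor, tracked separately as `fixed_log_w`, which cannot affect either
selection or the slope of ln w on F.

**Burn-in.** The "large initial population" is produced by evolving N = 500
individuals for 5000 generations (≈10 N, enough to reach mutation–selection–
drift equilibrium; a neutral run at these settings matches Watterson's E[S]
and E[π] to within sampling error, which the tests assert). Lost and fixed
sites are pruned each generation.

## Breeding schemes (the synthetic-data stage)

Lines are founded by sampling n individuals without replacement from the
ancestral population. At founding (t = 0, the base generation): the SNP panel
is frozen to sites segregating among the founders; mutation is switched off;
base allele frequencies are stored; and each founder haplotype receives a
unique allele at every tracer locus. Tracer loci sit on a uniform grid of one
locus per 0.5 Mb (4500 loci on the full genome, proportionally fewer on
scaled genomes), and F_IBD is the fraction of tracer loci at which an
individual's two labels coincide — by construction, identity of labels is
identity-by-descent relative to the base generation.

* **RC** (random contributions): N offspring, each from two distinct
  fitness-proportionally drawn parents.
* **EC** (equalized contributions): random monogamous pairing into N/2
  couples, exactly two offspring per couple. Natural selection can only act
  within family, implemented as offspring viability: a candidate offspring is
  accepted with probability equal to its relative fitness (w_max = 1 on the
  segregating-loci scale) and its gametes are redrawn on rejection, with a
  retry cap that aborts with a diagnostic if a couple cannot produce viable
  offspring.
* **SEL**: truncation selection on own phenotype for a neutral quantitative
  trait. The founding step samples T individuals (the base population) and
  selects the top N = 20% by phenotype; every later generation the N parents
  produce T candidates as under RC and the top N are selected (a stationary
  scheme with constant selected proportion — the founding-only alternative
  would let selection act just once). Only selected candidates enter the
  pedigree.

**Trait.** A random 5% of panel SNPs are QTL; derived-allele effects are
N(0, 0.1²), gene action additive within and between loci; phenotype =
genotypic value + N(0, V_E) with V_E = 2. The realized base heritability is
reported per replicate rather than forced to a target: with ~5% of a large
SNP panel as QTL the implied h² depends on the panel size, and on strongly
scaled-down genomes it is far below one half. QTL and fitness loci are
excluded from the marker panel handed to the estimators.

## Inbreeding measures

The six frequency-based formulas (VR1/VR2, YA1/YA2, LH1/LH2) are implemented
exactly as printed (see the module docstring of `inbredsim.estimators`),
along with F_HOM, F_q05 = 2F_HOM − 1, Wright's F_PED via memoized kinship
recursion (equivalent to the tabular method; parents must precede offspring,
which also excludes cycles), F_IBD from tracers, and window-based ROH.

**Panel policy.** Base-frequency mode uses all SNPs segregating in the base
generation (monomorphic-in-current SNPs retained — base frequencies keep the
denominators finite); current-frequency and p = 0.5 modes use SNPs
segregating in the current generation (otherwise 2pq = 0 terms are undefined;
the source text states this panel only for F_HOM/F_q05, extending it to the
other current-frequency estimators is a design choice). A frequency of
exactly 0 or 1 inside a panel raises an error rather than propagating NaNs.
The counted allele is immaterial: all six estimators are exactly invariant
under x → 2 − x, p → 1 − p (asserted per individual in the tests). MAF
filtering removes SNPs with min(p, 1−p) ≤ threshold before estimation.

**ROH scan.** A window of 50 SNPs is homozygous if it has ≤1 heterozygote and
≤5 missing calls; a SNP is flagged if ≥5% of the windows covering it are
homozygous; maximal flagged runs are split at inter-SNP gaps >1000 kb and
kept if they have ≥100 SNPs (30 in the pig-style variant), length ≥1 Mb
(ROH-1) or ≥5 Mb (ROH-5), and ≥1 SNP per 50 kb (100 kb pig-style). The
parameters beyond the four stated ones are the cited tool's documented
defaults; all are exposed in `RohParams`. Segment length is end − start + 1;
F_ROH = Σ lengths / genome length. The scan is verified against a brute-force
window-enumeration oracle on constructed instances. Missing genotypes never
occur in simulated data; the allowance exists for real-data interop and is
unit-tested with synthetic missingness.

## ΔID, load, and comparisons

ΔID is the negated OLS slope of ln w on F over individuals with w > 0
(natural log — the convention consistent with lethal-equivalents arithmetic;
zero-fitness individuals are excluded and counted). Significance is a
two-sided t-test on the slope; power is the percentage of replicates with
P < 0.05. Replicate ΔID estimates are compared with the F_IBD-based ones by a
percentile bootstrap of the mean paired difference (reference − estimate,
positive = underestimation) and a paired t-test with documented degenerate
conventions (identical pairs → t = 0, p = 1).

The inbreeding load is B = Σ 2dpq with d = s(1 − 2h)/2, and V_A = Σ 2α²pq
with α = s/2 + d(1 − 2q), V_D = Σ (2dpq)². B equals the expected ΔID in the
absence of selection only to first order in s: the regression of *individual
log fitness* on F estimates Σ pq(2 ln(1−sh) − ln(1−s)) exactly (per-locus
genotype frequencies p² + pqF, 2pq(1−F), q² + pqF), which exceeds B when
strong deleterious alleles segregate. Both quantities are exposed
(`inbreeding_load`, `expected_delta_id`); the recovery test holds the
simulated ΔID to Monte-Carlo error of the exact expression and to a
proportional band around B.

## Gene dropping

An arbitrary acyclic pedigree TSV (id, sire, dam, cohort[, sex]) is accepted;
founders draw whole genomes from a simulated pool (without replacement by
default), every non-founder is formed from one recombinant gamete per
recorded parent, with neither mutation nor selection, and tracer labels make
F_IBD relative to the founding cohort. Per-cohort summaries support base-,
current- and 0.5-frequency provenances. A generator for pig-like synthetic
test pedigrees (many cohorts, parents reused across cohorts) stands in for a
real herd book, which is not shipped.

## Numerical and design notes

* **Reproducibility.** Every public entry point takes a NumPy `Generator` or
  seed; replicates derive independent streams from a master `SeedSequence`,
  and identical seeds reproduce results bit-for-bit (asserted).
* **Scaling.** Desk-scale runs shrink the genome (fewer or shorter
  chromosomes) while keeping every per-bp rate at its default; equilibrium
  diversity, and hence marker counts, scale linearly with genome length,
  which is also how the full-genome SNP count is obtained from a
  two-chromosome run. Problem sizes used by the test suite: an equilibrium
  N = 500 population on one 50-Mb chromosome (≈2800 SNPs), 120–500 replicates
  per Monte-Carlo comparison; the acceptance script uses two 125-Mb
  chromosomes (≈14,000 SNPs) and 250–500 replicates.
* **Tracer density.** F_IBD is itself a Monte-Carlo measurement; where a
  regression slope on F_IBD is the target (the load-recovery test), the
  tracer grid is densified to one locus per 100 kb so that label-sampling
  noise does not attenuate the slope. For comparisons of means the default
  density is ample.
* **Heterozygote excess.** With current-generation frequencies the
  frequency-based estimators average below zero. For unrelated sampled
  individuals the expectation is −1/(2n−1) (the self-kinship term in the
  sample frequencies); for a line of mutually related individuals the deficit
  roughly doubles, because the reference frequencies also absorb the shared
  drift. "Around −1/(2N)" is therefore an order-of-magnitude statement, and
  the tests treat it as such.
* **Degenerate inputs.** Constant-F regressions are flagged rather than
  raised; all-zero fitness raises; empty SNP panels raise; zero-variance
  estimator columns yield NaN correlations.

## What the generator does and does not emulate

The synthetic data reproduce the study conditions: equilibrium standing
variation with a realistic deleterious-effect distribution, LD generated by
real linkage on a finite genome, drift and purging in small lines, and exact
IBD bookkeeping. They do not emulate genotyping error or missingness (beyond
the ROH allowance), ascertainment bias of SNP chips, overlapping generations
in the discrete-generation schemes, separate sexes, or epistasis and
overdominance in fitness. Passing tests therefore validate estimator
behaviour under the model's assumptions, not under array-data artefacts.

## Scale dependence of the ΔID bias panel

The percent bias of mean ΔID relative to the load B, for samples of n = 100
drawn from the equilibrium population, is strongly genome-scale dependent.
On scaled genomes (i) B is dominated by the few deleterious alleles that
drift to intermediate frequency — a single locus can carry 10–15% of B — so
the bias denominator varies widely between independent burn-ins; and (ii)
with thousands rather than tens of thousands of markers, sampling noise in
F̂ inflates its variance and attenuates every regression slope, shifting all
biases downward. Both effects vanish roughly in proportion to genome length.
What is stable across scales, and what the test suite asserts, is the
ordering behind the biases: the rare-allele weighting of mean-of-ratios
estimators pushes ΔID from F_YA2 far above ΔID from F_LH1; MAF filtering
strips those rare alleles and lowers the F_YA2 estimate monotonically with
the threshold; and ratio-of-sums estimators are nearly indifferent to
filtering. The acceptance script reports the desk-scale magnitudes it
actually measures.

## Known limitations

Burn-ins at the full 2250-Mb genome are hours-long by design; the package
relies on the linear-in-length scaling argument (verified against neutral
theory) rather than running them routinely. F_PED's kinship recursion is
quadratic in the worst case for very deep, fully connected pedigrees, which
is adequate for ~10³–10⁵ records but not for national herd books. The EC
viability mechanism assumes fitness ∈ [0, 1] on the segregating-loci scale;
alternative normalizations (e.g. within-brood relative fitness) would purge
slightly differently.
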