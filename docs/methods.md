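# Methods

## The model

`introsim` is a discrete-generation, two-sex-optional Wright–Fisher forward
simulator built to study how deleterious variation shapes the genomic
landscape of introgressed ancestry after a single admixture pulse.  A run
proceeds through four phases:

1. **Burn-in.** One ancestral population of `N_A` diploids evolves for
   `10 N_A` generations starting from a mutation-free state, long enough
   for the selected mutational target to reach mutation–selection–drift
   balance.
2. **Split.** The population divides into a *donor* and a *recipient*
   subpopulation (both drawing their parents from the ancestral pool in
   the split generation); every haplotype is labeled with its
   subpopulation at this point, and those labels are inherited exactly
   through all subsequent meioses.
3. **Divergence.** The subpopulations evolve independently for `t_s`
   generations (default `2 N_A`), under per-model size schedules.
4. **Pulse and aftermath.** For exactly one generation, each parent of a
   recipient offspring is drawn from the donor pool with probability
   `f = 0.05`; the run then continues for `N_A` generations.  The
   realized initial introgressed fraction is therefore binomial around
   `f`.

Parents are sampled with replacement, with probability proportional to
fitness within their pool (soft selection at fixed census size).  Gametes
receive `Poisson(map length in Morgans)` crossovers placed in proportion
to the local recombination rate, and `Poisson(mu L)` new mutations at
uniform positions.  Within exons a new mutation is nonsynonymous with
probability 2.31/3.31, otherwise synonymous; outside exons it is neutral.
Only nonsynonymous mutations carry selection coefficients, drawn from a
gamma distribution of fitness effects (human preset: shape 0.186,
E[s] = −0.01314833; Arabidopsis preset: shape 0.185, E[s] = −0.00048655).

### Fitness

Fitness is multiplicative across loci.  A heterozygous site contributes
`1 − h|s|` and a homozygous site `(1 − 0.5|s|)²` (additive and h(s)
modes) or `1 − |s|` (fully recessive).  With `h = 0.5` this makes an
individual's fitness a function of its total number of deleterious
allele copies only, eliminating the spurious heterozygote advantage of
the textbook additive scheme, whose two-heterozygote configuration beats
the one-homozygote configuration by exactly `0.25 s²` — an artifact that
would masquerade as heterosis in admixed individuals.  The textbook
scheme (`additive_textbook`) is retained solely as a comparison arm: the
test suite verifies that the nonsynonymous site-frequency spectrum of an
equilibrium population is statistically indistinguishable between the two
formulations.

The h(s) dominance model is the hyperbola `h(s) = h₀ / (1 − B s)`
(`h₀ = h(0)`): the human estimate is `0.5 / (1 − 7071.07 s)`; the
Arabidopsis estimate `1 / ((1/0.987) − 39547 s)` is the same hyperbola
with `(h₀, B) = (0.987, 0.987·39547)`.  Dominance decreases monotonically
with effect size, so strongly deleterious mutations are nearly recessive.

Selection coefficients are stored signed (`s ≤ 0`); fitness formulas
consume `|s|`.  Factors are clipped at 0; draws with `|s| > 1` are counted
(`MutationTable.n_clipped`) because rescaling can push the gamma tail past
the lethal boundary (see *Rescaling* below).

Mutations fixed in every extant population are pruned periodically (every
100 generations and before any recorded statistic), because globally
monomorphic sites cannot differentiate the populations; pruning divides
every cached fitness by the same constant, so relative fitness — the
quantity that drives both selection and the reported `w_R/w_D` — is
exactly invariant.

### X-linked mode

In X mode males are hemizygous (one X, transmitted to daughters without
recombination), sexes alternate 1:1, and fitness is dosage-compensated: a
carrier male has the fitness of a homozygous female, and in the additive
model heterozygous females are intermediate.  Only females recombine.

### Mating systems

Partial selfing is a per-population probability that an offspring's two
gametes come from a single (fitness-weighted) parent.  The ancestral
population is outcrossing; selfing probabilities apply to the two
subpopulations independently, which is what the outcrosser-vs-selfer
grid varies.

### Chromosome structure

Random structures alternate intergenic blocks (Uniform(100, 5000) bp)
with genes built as an exon followed by (intron, exon) pairs appended
with probability 0.8 — so genes start and end with exons.  Exon lengths
are Lognormal(meanlog = log 50, sdlog = log 2) and intron lengths
Lognormal(log 100, log 1.5); the second printed parameter is read as the
log-scale standard deviation (the convention of the recipe this
construction follows), which leaves the medians (50 bp, 100 bp) —
the quantities the tests pin down — unaffected.  About 8% of a random
chromosome is exonic.  Real annotations can be loaded from BED (exons
merged; non-exonic gaps collapse to one neutral class) with a
two-column position/rate recombination map; nothing is downloaded.

### Ancestry tracking

Every haplotype carries run-length-encoded ancestry segments; these are
spliced exactly at crossover breakpoints, so the segment-based
introgressed fraction `p_I` is exact, not an estimate.  A marker-based method
is also implemented: neutral marker mutations at
500-bp spacing are stamped on every donor haplotype immediately before
the pulse, and `p_I` is estimated as the mean marker frequency (globally
or per 100-kb window).  The two agree up to tract-boundary effects at the
marker spacing — the test suite bounds their mean absolute per-window
difference by spacing/window.  Introgression deserts are maximal
intervals where no sampled haplotype carries donor ancestry, validated
against a per-base-pair scan.

## Rescaling and the desk-scale profile

Forward simulation at full scale (N_A = 10,000; 130,000
generations; 5–100 Mb) is cluster-scale.  The package implements the
standard rescaling: sizes `N/c`, times `t/c`, selection `s·c`, mutation
`μ·c`, and per-bp recombination `r → 0.5(1 − (1 − 2r)^c)` (≈ `rc` for
small `r`), with sequence length unchanged.  The test suite verifies on a
miniature donor-favoring model that `c` and `2c` runs give statistically
indistinguishable ancestry outcomes.

The default experimental profile is a desk-scale replica of the study
conditions: the full-scale parameter values on a 500-kb randomly structured
chromosome, with a total scaling of `c = 100` (equivalently: the
N_A = 500 profile is the full-scale demography at c = 20, with a further
factor 5 applied), i.e. runs of 100 diploids over ~1,300 generations.
Two distortions of this choice are measured and documented rather than
hidden:

- **DFE truncation.** At `c = 100` the scaled human DFE has
  P(|s·c| > 1) ≈ 0.26; that tail becomes lethal-equivalent.  These
  variants are rare per gamete and rapidly purged, but under recessive
  fitness they deepen masked load, so heterosis-driven quantities are
  somewhat exaggerated and hemizygous (X) purging is strongly
  exaggerated: the autosome/X introgression fold comes out around 3–6
  rather than the full-scale ~1.5 (the direction, autosome > X, is
  robust).
- **Chromosome length.** Chromosome-scale selection differentials are
  proportional to the per-chromosome mutational target.  A 500-kb desk
  chromosome carries roughly one tenth of the 5-Mb selection
  differential, so the additive Model 4 ancestry surge saturates near
  20–30% rather than the full-scale 75%; the recessive analog, driven by
  per-site masking, still reaches ~40–60%.

The neutral calibration (ancestry martingale) runs unscaled at
N_A = 200 on 100 kb, where the exact binomial/Wright–Fisher single-locus
oracle applies.

Because neutral and synonymous mutations never feed back on the
dynamics, experiments that need no neutral-site statistic set
`track_neutral=False` and simulate only the exonic nonsynonymous target
(the usual tree-sequence-style economy of treating neutral variation
as an overlay).  An A/B comparison on
matched replicates shows no detectable difference in ancestry or load
trajectories.  Runs that compute F_ST, the full SFS, or private/shared
counts keep full neutral tracking.

## Statistics

- **Load**: per-population arithmetic mean fitness over segregating
  selected sites, the ratio `w_R/w_D`, derived deleterious sites per
  haplotype, and homozygous deleterious sites per individual.
- **F_ST**: Hudson per-site estimator
  `num = (p₁−p₂)² − p₁(1−p₁)/(n₁−1) − p₂(1−p₂)/(n₂−1)`,
  `den = p₁(1−p₂) + p₂(1−p₁)`, combined across sites as a ratio of sums
  (never an average of ratios); negative per-site numerators are
  retained.  Tested against an independent heterozygosity-route identity
  to 1e-12.  Marker mutations are excluded everywhere.
- **SFS**: derived-allele counts with everything at count ≥ 25 pooled
  into the last bin.
- **Window correlations**: Spearman's ρ with ties broken by a seeded
  random permutation, Pearson correlation of the
  ranks, and a two-sided large-sample t p-value.  Note the randomized
  tie-break attenuates |ρ| slightly relative to midranks.

## Numerical and design choices

- Coordinates are 0-based, half-open throughout; BED dialect matches.
- One root seed per replicate; all replicate and structure seeds derive
  deterministically from the experiment root seed, so grids re-run
  byte-identically and cells never share random streams.
- Infinite-sites within a gamete: a mutation landing on an occupied
  position of that gamete is re-drawn.
- A split time of 0 collapses to a pulse in the first post-split
  generation (one generation is the minimum resolvable divergence).
- The pulse acts on parent choice only, for exactly one generation;
  realized ancestry is binomial around `f`.
- Windows with no marker report NaN rather than 0.
- Model presets: 0 — equal constant sizes; 1 — recipient bottleneck to
  `N_A/10` for the final `0.1 N_A` generations before the pulse;
  2 — donor at `N_A/10` from the split; 3 — recipient at `N_A/10` from
  the split; 4 — recipient at `N_A/10` from the split, restored at the
  pulse.  All schedules are config-exposed.

## Problem sizes used by the shipped checks

The test suite and `scripts/acceptance.py` use the desk profile with
replicate counts of 16–50 per cell (each check's Monte-Carlo precision
is far inside its tolerance at these counts); the high-recombination
control (r = 1e-6 analog, ~50 Morgans per gamete after scaling) uses the
smallest counts because each meiosis shreds every haplotype.  All sizes
are stated in the scripts themselves.

## What desk-scale results do and do not show

Passing desk-scale checks demonstrate the mechanisms — heterosis from
masked recessive load, donor-load-dependent direction of selection on
ancestry, recombination-rate dependence, X-autosome asymmetry, selfing
effects — under the full-scale parameter values, at reduced genome size
and census.  They do not reproduce the full-scale magnitudes that grow
with chromosome length (the 75% additive Model 4 surge, the ~1.5-fold
X/A ratio), and quantities dominated by the strong tail of the scaled
DFE should be read qualitatively.  Real genomes additionally have
heterogeneous recombination maps and gene density, which the random
structures only emulate statistically.
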