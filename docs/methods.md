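# Methods

## The test

For one biallelic variant in one population the data are the called
genotype counts (n_AA, n_AB, n_BB) plus the number of missing calls.  The
allele-A frequency is estimated from the same counts, m = (2n_AA +
n_AB)/2n with n the called total, and the statistic is the 3-category
Pearson goodness of fit of the observed counts against the binomial
expectations (n·m², 2n·m(1−m), n·(1−m)²).

**Degrees of freedom.** The default converts χ² to p with **2** degrees
of freedom, for which p = exp(−χ²/2) in closed form.  The conventional
HWE test subtracts the one estimated parameter and uses 1 df; it is
available via `dof=1`.  The 2-df default was chosen because it reproduces
every printed p-value of the worked-example table this package ships to
its stated precision; it is conservative as a null test (at α = 0.01 it
flags ≈ 0.2 % of null simulations, versus ≈ 1 % for the 1-df test, which
is the calibrated choice — the calibration test in the suite uses
`dof=1`).  Direction is read from the observed/expected heterozygote
ratio O/E = n_AB / 2n·m(1−m): significant departures (default
α = 10⁻⁵) with O/E < 1 are LoH, O/E > 1 GoH.  A significant departure
with O/E exactly 1 has no direction and is labelled UNDEFINED, as are
monomorphic distributions — these must not be counted as "in HWE"
controls, so they are never given p = 1.  No continuity correction is
applied (the printed reference values reproduce without one).

**Filters.** A variant is excluded when its pooled call rate (called/N,
N the cohort size) is below 0.80 or its pooled folded MAF below 0.01;
included variants are dropped from any population whose own folded MAF is
below 0.001.  "Strict mode" re-runs with call rate ≥ 0.98 — the
high-quality subset in which error-driven GoH departures disappear while
biology-driven LoH persists.

## Explanatory features

Five variables per variant: missing-genotype fraction (denominator N);
variant type — SNP (both alleles 1 bp) vs indel (lengths differ);
equal-length multi-base substitutions are typed OTHER and excluded from
SNP/indel contrasts rather than silently binned; overall folded MAF from
pooled counts; **MAF-SD**, the cross-population standard deviation of the
*unfolded* allele-A frequencies with divisor N (population SD) — folding
would conflate substructure with allele-label flips, and this convention
reproduces both printed reference values (0.23, 0.12) where folded or
divisor-(N−1) variants do not; and CNV overlap, point-in-interval of the
variant's 1-based anchor position against 0-based half-open loss/gain
intervals (deletion-spanning logic for long indels is out of scope).
MAF-SD and missingness are fractions internally; the report layer prints
percent.

## Group comparisons

The unit of analysis is one variant × population genotype distribution;
LoH and GoH distributions are compared against in-HWE controls per
feature.  Continuous features use the two-sided Mann-Whitney U — exact
enumeration when both groups have ≤ 20 tie-free values, the tie-corrected
normal approximation otherwise.  Categorical 2×2 features use Pearson
chi-square without continuity correction when all expected cells are
≥ 5, else Fisher's exact test; a zero margin returns p = 1 with a
warning.  Heterogeneity of departure counts across populations is the
2×K chi-square (departure vs control by population, K−1 df); a 3×K
variant (control/LoH/GoH jointly) can be formed by two calls.  No
multiple-testing correction is applied: the report is descriptive QC, and
variant-level features replicated across populations induce
pseudo-replication, so p-values should be read as screening evidence.

## Region scans

A scan tests every variant of a region in one population, keeping
variants with folded MAF > 0.01, and emits a track of −log₁₀ p (capped
at 320 so underflowing p = 0 stays plottable; the cap value is a module
constant) and O/E.  Clusters are greedy merges of significant variants
whose neighbours lie within 10 kb, reported when ≥ 5 significant members;
by default only direction-pure clusters are returned (both reference
phenomena — deletion LoH blocks and the paralog GoH peak — are pure).
The 10 kb/5 defaults are exposed; they comfortably capture the reference
geometry of 11 constitutively heterozygous sites on a 2.4 kb fragment.
Tracks record whether the source data contained any missing genotypes at
all; force-called panel data (every sample genotyped, even inside
homozygous deletions) make the missingness feature uninformative and the
flag warns downstream consumers.

## Synthetic cohorts

The generators draw one multinomial per distribution, all randomness from
one seeded `numpy.random.Generator` per call, and every generator
reduces *exactly* (same seed, same draw) to the HWE generator when its
distortion parameter is zero, by delegation.  Closed-form heterozygote
O/E ratios used as oracles: inbreeding 1−F; stratification
Σw·2p_kq_k / 2p̄q̄ (Wahlund); deletion overlay (1−d)/(1+d) when
homozygous-deletion carriers are missing (exome-like) and (1−d)² when
they are force-called homozygous (panel-like) — the deletion and SNP
alleles are drawn independently (linkage is real but unmodelled);
paralog collapse calls a fraction of individuals heterozygous regardless
of genotype (O/E = 2, χ² = n at fraction 1).  Allelic dropout is modelled
**per allele**: each allele of each individual independently fails at
rate e; a heterozygote with one surviving allele is called homozygous
for it, with none missing.  This literal dropout process *reduces*
observed heterozygosity (the exact call probabilities are enumerable and
tested); spurious heterozygote excess in real data is attributed to
cross-hybridization and indel miscalls, which the paralog generator
models.

The region simulator places variants uniformly (optionally forcing a
count inside an interval, for dense paralog runs), applies each layout
interval's mechanism to the variants inside it, and emits count tables,
a GT-only VCF 4.2 with per-sample genotypes consistent with the counts
(byte-identical under a fixed seed), and a truth BED.  The
multi-population cohort generator emulates an exome-style extract: six
populations of 2,000 individuals, ~80 % of variants in HWE, ~10 % LoH
via two-way stratification at sub-population frequencies p ± 0.3 (clean
genotyping, so these survive strict mode), ~10 % GoH via paralog collapse
(het fraction 0.8) with 15 % missingness and indel alleles — tying the
error signature to low call rate and indel type as observed in real
cohorts.  What the simulations do **not** emulate: linkage disequilibrium,
allele-frequency spectra, selection, genotyping-batch structure; passing
tests demonstrate the statistics and the mechanism arithmetic, not
performance on any particular real dataset.

## Problem sizes and numerical choices

The suite and acceptance checks run at desk scale chosen to make the
Monte-Carlo bounds sharp: 10⁵ replicates for calibration (vectorized),
n = 10⁵ individuals for closed-form O/E identities (3 Monte-Carlo SE
bands, SE from the binomial numerator), n = 5,000 individuals × 500
variants for end-to-end region recovery.  Cohort-scale census counts of
the source studies require their full datasets and are out of scope.
Exact Mann-Whitney and Fisher p-values are cross-checked against
combinatorial enumeration oracles; the chi-square statistic against
exact rational arithmetic for all distributions with n ≤ 12.  p-values
are serialized at full precision in machine files and at 2 significant
figures in report output; expected counts round to integers and O/E and
frequencies to 2 decimals in reports only.

## Known limitations

Multi-allelic and X-chromosome/hemizygote-aware testing are out of scope
(multi-allelic VCF records are skipped and counted).  Exact
(enumeration-based) HWE tests are not implemented; at the sample sizes
this package targets the chi-square approximation is adequate, and rare
variants are excluded by the MAF filter before testing.  CNV overlap uses
the variant anchor position only.  The association report's
pseudo-replication (variant-level features repeated per population) is
inherent to its distribution-level design and is documented rather than
corrected.
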