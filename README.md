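# hwescan

Directional Hardy-Weinberg-departure testing for genotype quality control.

Departure from Hardy-Weinberg equilibrium (HWE) is a standard red flag in
GWAS QC, but it is an unspecific one: genotyping error, common deletion
polymorphisms, population substructure and inbreeding all produce it.  The
direction of the departure carries the diagnostic information.  `hwescan`
tests each variant × population genotype distribution for HWE departure
and splits significant departures by the observed/expected heterozygote
ratio:

* **LoH** (loss of heterozygosity, O/E < 1) — points at real biology:
  SNPs inside deletion polymorphisms (hemizygotes are called homozygous),
  hidden population stratification (Wahlund effect), inbreeding;
* **GoH** (gain of heterozygosity, O/E > 1) — the genotyping-error
  signature: indel miscalls, allelic dropout asymmetries and
  paralog cross-hybridization that makes every individual appear
  heterozygous.

For a biallelic variant with called genotype counts (n_AA, n_AB, n_BB),
n = n_AA + n_AB + n_BB, the allele-A frequency is estimated as
m = (2·n_AA + n_AB) / 2n and the test is the 3-category chi-square
goodness of fit against the expected counts (n·m², 2n·m(1−m), n·(1−m)²).
By default p-values use 2 degrees of freedom (for which p = exp(−χ²/2));
`dof=1` gives the conventional test that subtracts the estimated
parameter.  A departure is declared at p < 10⁻⁵ and labelled by
O/E = n_AB / 2n·m(1−m).

On top of the per-distribution test the package provides:

* the standard inclusion filters (pooled call rate ≥ 80 %, pooled minor
  allele frequency ≥ 1 %, per-population MAF ≥ 0.001, and a strict
  ≥ 98 % call-rate re-analysis mode);
* five per-variant explanatory features (missingness, SNP/indel type,
  overall MAF, cross-population allele-frequency SD, CNV loss/gain
  overlap) and a feature-association report comparing LoH and GoH groups
  against in-HWE controls (Mann-Whitney / chi-square / Fisher);
* region scans producing plot-ready tracks of −log₁₀ p and O/E, greedy
  cluster detection of departure runs (deletion LoH blocks,
  paralog-collapse GoH peaks), and inside/outside interval summaries;
* seeded synthetic-data generators for each causal mechanism (HWE,
  inbreeding F, K-subpopulation stratification, deletion overlay,
  paralog collapse, per-allele dropout) with ground-truth labels,
  count-table/VCF/BED writers, and a region simulator.

## Worked example

Three published example variants (genotype counts across the six ExAC
super-populations) ship with the package:

```python
from hwescan import HWEDepartureModel, datasets

res = HWEDepartureModel(datasets.example_variants()).fit()
print(res.summary())
```

```
Directional HWE-departure analysis
==================================
variants supplied:            3
variants passing filters:     3
genotype distributions:       18
alpha: 1e-05   dof: 2   strict call-rate mode: False

classification counts:
  NONE            6  ( 33.3%)
  LOH             6  ( 33.3%)
  GOH             6  ( 33.3%)
  UNDEFINED       0  (  0.0%)

significant departures by population:
  AFR    GOH      1
  AMR    GOH      1
  AMR    LOH      2
  EAS    GOH      1
  EAS    LOH      2
  FIN    GOH      1
  NFE    GOH      1
  NFE    LOH      1
  SAS    GOH      1
  SAS    LOH      1
```

Each variant illustrates one mechanism.  `rs7551421` sits inside a common
deletion polymorphism: it departs from HWE with heterozygote *deficit*
(LoH) in four populations — e.g. East Asians show 1,463 heterozygotes
against 1,692 expected, O/E = 0.86, p = 8.4×10⁻¹⁸ — and is in HWE in the
two populations where the deletion is absent.  `rs509360` has strongly
different allele frequencies across populations (cross-population SD
0.23): pooled sub-structure drives LoH in East Asians and Latinos.
`rs58896934` is an insertion/deletion variant with 17 % missing
genotypes: every population shows heterozygote *excess* (GoH, O/E
1.13–1.24), the error signature, and the calls vanish in the strict
≥ 98 % call-rate mode.  All per-cell numbers (expected counts,
frequencies, O/E, p) are in `res.results`; `res.report_frame()` rounds
them to report precision.

The same analysis runs from the shell:

```bash
hwescan simulate --out-dir sim          # mechanism-labelled synthetic region
hwescan pipeline --counts sim/counts.tsv --out-dir out --scan-population POP
```

which writes `results.tsv`, `features.tsv`, `association.tsv`, a scan
`track.tsv`, `clusters.bed` and a JSON run log.

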