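# Methods

`silkymap` implements the inference chain by which a fully penetrant
recessive Mendelian trait is mapped to a single candidate regulatory
variant: segregation testing and two-point linkage in an F2 intercross,
identical-by-descent (IBD) haplotype-sharing fine mapping with a
causal-variant exclusion filter and complete-association tabulation, a
pooled-sequencing fixation scan, and the downstream expression statistics
(2^−ΔΔCt, allelic expression imbalance, dual-luciferase normalisation).
This note records the models, the parameter choices and their rationale,
and what the synthetic-data generators do and do not emulate.

## Coordinate conventions

All positions are 1-based and inclusive at both ends, the convention in
which assembly coordinates are quoted in mapping studies.  Interval length
is `end − start + 1`; at the kb scale reported for mapping intervals the
±1 bp convention is invisible after rounding (half-up, one decimal).  BED
export converts to 0-based half-open coordinates and a write/read round
trip is the identity.  Promoter-variant positions are also expressed
relative to the A of the initiator ATG (+1), with negative offsets
upstream and no position 0, which is how the package ties the genomic
position of a promoter SNP (−103) to a transcription start site (−90).

## Two-point linkage in an F2 intercross

The trait is autosomal recessive with full penetrance; markers are
codominant and biallelic.  With the trait allele *h* coupled to marker
allele B in the F1, F1 gamete frequencies are hB = HA = (1 − θ)/2 and
hA = HB = θ/2.  An F2 offspring is two independent gametes
(sex-averaged θ), and because the phenotype pools the HH and Hh trait
genotypes, each marker reduces the data to a 6-cell count table of marker
genotype {AA, AB, BB} × phenotype {wild-type, case}.  The likelihood is
the product of the six class probabilities; θ̂ maximises it on [0, 0.5]
and LOD = log₁₀ L(θ̂) − log₁₀ L(½).

Numerics: a 501-point coarse grid brackets the optimum, golden-section
search (tolerance 1e-6) refines it, and the endpoints 0 and ½ are always
evaluated exactly, with ties broken toward smaller θ.  The bracketing step
makes the estimator agree with an exhaustive 1e-4 grid even on flat or
boundary-maximised likelihoods; boundary solutions are returned, never
raised.  Marker allele phase is not assumed in the scan: both
orientations are evaluated and the better-supported one reported, which
leaves the LOD invariant to allele-label swaps.  Monomorphic or
all-missing markers are flagged non-informative rather than failing the
scan.  The per-marker LOD values of the original study are not
reproducible from published information (they require individual-level
genotypes), so the machinery is validated by oracle agreement and by
recovery of the true θ at the study's sample size (n = 229) instead.

The segregation test is an ordinary Pearson χ² of the phenotype counts
against the Mendelian 3:1 expectation (df = 1), via `scipy.stats`.

## IBD fine mapping

A recessive affected individual is autozygous around the causal locus, so
the causal region lies inside a haplotype that all cases carry
homozygously.  Genotypes are stored unphased; homozygous calls make the
case haplotype directly readable, which is the device the whole procedure
rests on.  The steps are deterministic set operations:

* **Shared blocks** — maximal runs of consecutive markers at which every
  case is homozygous for one common allele.  A missing call is
  *compatible* with sharing by default (it neither breaks nor supports a
  run); a `breaking` policy is available.  A `max_case_exceptions`
  parameter (default 0, strict) makes any tolerated per-marker discordance
  explicit rather than silent.
* **Control exclusion** — a block is excluded iff at least one control is
  homozygous for the shared allele at every marker of the block where it
  has a call (the full haplotype, not a sub-block).
* **Boundary narrowing** — heterozygous (or opposite-homozygous) calls in
  an extended case panel mark markers where the shared haplotype has been
  lost to historical recombination.  The refined interval starts 1 bp
  inside the outermost discordant marker on each side (het-exclusive
  convention).  If discordance splits the block, the longest clean segment
  is kept (ties toward the proximal side); a side with no informative
  discordant marker keeps the block coordinate and is flagged open.
* **Variant exclusion filter** — a variant is retained iff all cases share
  one homozygous genotype, no control is homozygous for that genotype, and
  every obligate heterozygote is heterozygous; the first violated clause
  and a witness individual are reported per excluded variant.
* **Association tabulation** — per-population genotype counts at a
  candidate variant with a complete-association predicate (cases one
  homozygote, controls the other, obligate hets heterozygous; missing
  calls tabulated separately and excluded from the predicate).

No multiple-testing correction is applied anywhere in this chain: it is
deterministic filtering, not hypothesis testing.

## Pooled-sequencing fixation scan

Per site, the variant allele frequency is alt/(alt+ref) where coverage is
at least `min_coverage` (default 4 reads); lower-coverage sites are
undefined, not zero.  Fixed runs are maximal sequences of defined sites
with VAF ≥ `fixation_threshold`, tolerating up to `max_gap_sites` interior
failures (default 0) and discarding runs with fewer than `min_sites`
passing sites (default 5).  The default threshold is 0.95 rather than 1.0
to tolerate pooled-sequencing error; the strict setting is one argument
away.  Allele polarity is taken from the input; no re-polarisation against
an ancestral allele is attempted.

## Expression statistics

* **2^−ΔΔCt** — technical replicates are averaged per individual and gene;
  ΔCt = Ct_target − Ct_reference per individual; ΔΔCt per group is the
  group-mean ΔCt minus the reference group's mean (the standard Livak
  formulation), so the reference group's fold is exactly 1.  Group tests
  are on ΔCt values, the statistically standard choice when the original
  analysis does not state whether tests were on ΔCt or fold.
* **Allelic expression imbalance** — within a genotype, cDNA vs gDNA
  major-allele fractions are compared paired on individual; cDNA fractions
  are compared between genotypes unpaired.  For homozygotes the same
  cDNA-vs-gDNA comparison quantifies assay signal bias (there is no allele
  contrast).  Results are invariant to complementing the fractions
  (relabeling which allele is "major").
* **Luciferase** — per well, firefly/renilla; per construct and biological
  repeat, the mean of technical-replicate ratios divided by the reference
  construct's mean in that repeat, making activity invariant to rescaling
  a repeat's luminescence.  Means and SDs are over biological repeats;
  pairwise tests run on per-repeat activities.

Welch's unequal-variance t-test is the default wherever "Student's
t-test" leaves variance pooling unspecified; a pooled flag is exposed.
Exactly constant degenerate inputs (zero variance) report p = 1 when the
groups coincide and p = 0 when they differ, rather than NaN.

## Synthetic data: what is emulated, and what is not

All generators derive independent child streams from one integer seed and
are bit-reproducible.

* **F2 intercross** (defaults: 229 F2, 22 markers, full penetrance) —
  founders fixed for alternative alleles, F1 phase known, gametes by the
  Haldane map function (no interference, sexes equal), genotyping error a
  uniform flip to another state, missingness uniform.  1 cM defaults to
  330 kb, a chicken-like genome average.  Not emulated: crossover
  interference, sex-specific maps, family structure beyond a single
  phase-known F1 pair (family count is a parameter of the study design the
  original analysis does not disclose).
* **Breed panel** (defaults: 76 cases, 95 controls, 34 markers across the
  ~43 kb candidate region, planted haplotype = the candidate interval) —
  each case carries the ancestral haplotype minus an exponential erosion
  per side (mean 0.0025 cM ≈ 0.8 kb), a standard descent-segment
  approximation for a deeply ancestral haplotype shared across breeds;
  controls are Hardy–Weinberg draws from per-marker background
  frequencies (default Uniform(0.1, 0.9)).  Genotyping error defaults to
  0 (array-genotyping class accuracy) and missingness to 2%.  Not
  emulated: coalescent breed history, linkage disequilibrium among
  background markers, selection.
* **Pool counts** (defaults: 500 sites over the ~182 kb combined linkage
  region, coverage Poisson(20), pool of 15) — sites inside the planted
  interval have frequency 1; background frequencies are Uniform(0.1, 0.7),
  since sites ascertained as segregating in a small pool rarely sit near
  fixation outside IBD tracts.  Not emulated: read alignment and calling,
  sequencing error beyond the binomial draw, ascertainment of the site
  list itself.
* **Expression tables** — Gaussian replicate draws at the reported group
  sizes and effect scales (e.g. n = 11 heterozygotes with cDNA fraction
  0.65 vs gDNA 0.50; promoter constructs at ~46× and ~8× the reference).
  Not emulated: plate effects, amplification-efficiency deviations,
  pyrogram-level signal artifacts.

Because the generators contain none of the real data's LD structure,
ascertainment or batch effects, passing recovery tests demonstrates the
correctness of the inference chain under its own model assumptions — not
the power of the original study design on real chickens.

## Problem sizes in the validation suite

The test and acceptance runs use the study's own sample sizes where they
matter (229 F2; 76/95 panel; n = 11 heterozygotes; coverage-20 pools) and
package-chosen replication counts elsewhere: 1000 random count tables for
grid-oracle agreement, 200 replicates per θ for recovery, 10⁴ random
matrices for block-finder/oracle equivalence, 100 seeds for each planted
recovery experiment, 1000 null simulations for test calibration.

## Known limitations

* Two-point only; no multipoint likelihoods or interference models.
* The IBD engine is exact-sharing based; no probabilistic autozygosity
  HMM, phasing or imputation, so single genotyping errors in a case break
  a block unless `max_case_exceptions` is raised.
* Microsatellites are handled only after biallelic recoding.
* VCF support is GT-only and biallelic; multi-allelic records are
  rejected, not split.
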