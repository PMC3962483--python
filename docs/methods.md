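# Methods

This note documents the models, estimators and numerical choices behind
`medpopgen`, and what its synthetic-data generator does and does not
emulate.

## The system being modeled

The package targets the population-genomic characterization of a wild
medaka (*Oryzias latipes*) founder population and a panel of inbred
laboratory strains: per-bp heterozygosity around 1.5 × 10⁻³ in the wild
sample versus ~3 × 10⁻⁵ in inbred lines, short-range linkage
disequilibrium (haplotype blocks of a few hundred bp), recent positive
selection detectable by iHS, and tests of historical gene flow between
Southern, Northern, Korean and Taiwanese populations polarized by a
distant outgroup (stickleback).

## Synthetic data

Ancestry is simulated with msprime (Hudson coalescent); mutations use a
binary infinite-sites model so every site is biallelic with a known
ancestral allele. Defaults are chosen so the simulations live at the
study's parameter point:

| parameter | default | rationale |
|---|---|---|
| mutation rate μ | 2.5 × 10⁻⁸ /bp/gen | the rate used for all demographic scaling |
| effective size Nₑ | 15,000 diploids | 4Nₑμ = 1.5 × 10⁻³, the wild heterozygosity |
| recombination rate r | 2.5 × 10⁻⁸ /bp/gen | ≈ 1 cM/Mb, a typical teleost genome average |
| sample | 48 haplotypes | 24 wild diploids (eight trios' founders + spares) |

What the generator does **not** emulate: genotyping error and missingness
structure of real short-read calls, variable recombination/mutation along
the genome, gene conversion, sex chromosomes, and the reference biases of
a real assembly. Tests passing on these simulations therefore validate
the *estimators* under their stated models, not robustness to those
artifacts.

Component models:

- **Trios / inbred lines.** Offspring are explicit meiotic products:
  Poisson(rL) crossovers at uniform positions, random starting phase.
  Trio output is Mendelian-error-free by construction (the checker
  verifies this). Brother–sister inbreeding follows the classical
  full-sib recurrence; expected heterozygosity after g sib matings decays
  asymptotically by λ = (1+√5)/4 ≈ 0.809 per generation, which the test
  suite verifies to within 10% over 500 replicate lines. On a single
  simulated chromosome residual heterozygosity is close to all-or-nothing
  (one linkage block), so summaries average over many replicate lines;
  real genomes average over chromosomes instead.
- **Sweeps.** Rather than forward selection, a core haplotype is copied
  onto `round(target_freq × n)` carriers (ties toward more carriers) over
  flanking tracts with exponentially distributed per-side lengths. The
  tract mean corresponds to 1/(rT) for a sweep T generations old; the
  100-kb default represents a sweep a few hundred generations old —
  recent enough to still segregate at intermediate frequency with a
  strong haplotype signature.
- **Admixture quartets.** Four populations (((P1,P2),P3),O) with splits
  at 5, 20 and 100 kilogenerations and an optional pulse from P3 into P2
  at 500 generations. Sites are polarized by requiring the outgroup
  sample to be monomorphic and recoding that state as ancestral, so the
  outgroup is fixed ancestral at every retained site.
- **Microsatellites.** Allele frequencies are Dirichlet per locus;
  genotypes are a mixture of Hardy–Weinberg draws and forced homozygotes
  with mixture weight F, giving E[H_obs] = (1−F)·H_exp exactly.
- **Morphometrics.** Ratio traits (lateral L1–L3 over body length L4,
  dorsal D1–D4 over D5) carry a between-strain variance fraction h² and
  are multiplied back by each fish's body length, so body size dominates
  raw variance as in real larval imaging.
- **Consensus calls.** Planted 'N' gaps and discrepant bases with
  assigned qualities, plus a truth table, for patch-recovery testing.

## Estimators and procedures

**Reference patching.** 'N' positions with any unambiguous consensus call
are filled regardless of quality; discrepant positions are revised only at
quality ≥ 100 in thresholded mode and always in unthresholded mode.
Ambiguous (IUPAC) calls never revise — sites with support for two bases
stay as they are. Validation metrics: concordance of revised bases with an
independent population panel (all-samples and any-sample fractions, with
uncovered records excluded from denominators) and the fold change in
agreement with an outgroup (ancestral) base, with a guarded undefined
result when no pre-revision base matched.

**Heterozygosity profiles and blocks.** Heterozygous calls per bp in 50-kb
non-overlapping windows by default (window/step configurable); the
wild-derived threshold is the quantile leaving a stated fraction (default
90%) of wild windows above it, and blocks are maximal runs of consecutive
above-threshold windows. Windows whose reference content is mostly N are
flagged as assembly gaps and excluded from threshold derivation.

**Inbreeding.** F = 1 − H_obs/H_exp with H_exp = 1 − Σpᵢ² from sample
allele frequencies, deliberately without small-sample correction; missing
genotypes leave both numerator and denominator; monomorphic loci are
undefined (NaN), negative F is reported as-is.

**Coding effects.** Strand- and frame-aware codon substitution per
overlapping transcript, with severity resolution
nonsense > stop-loss > missense > synonymous across transcripts. Expected
class fractions enumerate all nine single-nucleotide changes of each codon
weighted by codon frequency; stop codons are excluded from the source
weighting by default (exome codon usage describes sense codons) and can be
included by flag. Depletion is a one-sided binomial test
(observed ≤ expected) via the exact binomial CDF.

**LD and blocks.** All pair statistics come from directly counted phased
haplotype frequencies (no EM): D, r², D′ with the standard sign-dependent
D_max, and a log₁₀ likelihood-ratio LOD. The decay summary reports median
r² per distance bin (500-bp bins by default) and the first bin whose
median comes within 5% of the plateau level (median of the last 10 bins) —
an explicit stand-in for a visual plateau judgement. Gabriel blocks use
per-pair likelihood-profiled confidence bounds on |D′| (grid 0.001, allele
frequencies fixed at their MLEs, 5%/95% cumulative-likelihood bounds):
strong LD at bounds (0.70, 0.98), strong recombination below 0.90,
informative-pair strong-LD fraction ≥ 0.95, MAF ≥ 0.05, maximal candidate
spans kept greedily by length without overlap. Block span counts 1 bp at
each bounding marker.

**EHH / iHS.** EHH among n_c carriers is Σ_h C(n_h,2)/C(n_c,2) over
distinct extended haplotypes, computed by incremental partition refinement
(a numba kernel, O(carriers) per site step). iHH integrates each allele's
EHH curve by trapezoid in physical bp out to the EHH cutoff (default 0.05),
interpolating the crossing point; curves that reach a chromosome end above
the cutoff are flagged edge-truncated and excluded from scans.
Unstandardized iHS = ln(iHH_ancestral / iHH_derived) is standardized within
20 derived-allele-frequency bins. Standardization can take its bin
statistics from a separate (genome-wide) reference record set; a scanned
region containing a sweep should not supply its own bin statistics, since
hitchhikers contaminate their bins — the region-vs-genome distinction
matters on small simulated genomes and is the package's recommended usage.

**Composite sweep filter.** A SNP is retained when (1) |iHS| exceeds the
top-0.05% quantile (the absolute-threshold reading of this rule is exposed
as `abs_ihs_threshold`), and within a 20-kb window centered on it
(2a) the iHS standard deviation is at or below the median of all window
SDs, (2b) ≥ 4 window SNPs reach 80% of the window's max |iHS|, and
(2c) those SNPs are ≥ 10% of the window. Only negative-iHS clusters
(derived-allele sweeps) are kept; passing SNPs within one window width
merge into regions. The filter's quantile and window-dispersion criteria
are calibrated for genome-scale scans in which sweeps are rare: on a
small simulated chromosome that consists mostly of one sweep, the
sweep's own windows mix extreme and moderate values and raise both the
|iHS| quantile and the window-SD reference distribution, so the filter
is deliberately conservative there (its recovery tests use genome-like
record sets with a localized cluster). Conserved-region enrichment is a permutation test
drawing equally sized SNP subsets from all tested SNPs with the add-one
p-value estimator.

**Introgression.** Frequency-weighted ABBA/BABA weights
((1−p₁)p₂p₃ and p₁(1−p₂)p₃ with the outgroup fixed ancestral), D from the
weight sums, and a leave-one-block-out jackknife (1-Mb blocks by default)
for the SE; Z is withheld below a minimum block count. Single genomes are
the 0/1 special case. The ghost-population control restricts to sites
whose frequencies differentiate the test population from a named sister
panel (any difference by default; a floor is configurable) and recomputes
D on the subset.

**Phylogenetics and typing.** K2P distance with pairwise deletion of
ambiguous columns; saturated pairs (log arguments ≤ 0) are flagged rather
than extrapolated, and the distance-matrix builder substitutes the largest
finite estimate (an explicit underestimate) so tree construction can
proceed. Neighbor joining and midpoint rooting are delegated to scikit-bio
(negative branch estimates are disallowed/clamped there); the test suite
cross-checks topologies against an independent NJ implementation.
Majority-vote consensus breaks 50/50 ties to the reference allele and
flags them. Gower distances use dosage encoding |xᵢ−yⱼ|/rangeᵢ averaged
over co-called sites (categorical mismatch encoding by flag), with average
linkage by default. In-silico PCR honors circular templates and refuses
ambiguous multi-product amplifications; restriction digestion uses
canonical cut offsets (HaeIII GG^CC, MboI ^GATC, MspI C^CGG, RsaI GT^AC,
TaqI T^CGA) and mitotypes are equivalence classes of five-enzyme fragment
patterns binned to 20-bp gel resolution.

**Demography post-processing.** The PSMC parser keeps the final round's
atomic intervals (times, λ, θ₀). Scaling: N₀ = θ₀/(4μs) with bin size
s = 100 bp, Nₑ = λN₀, years = 2N₀·t·generation_years. Because a defensible
generation time for this system ranges from 0.67 to 1 year,
`generation_years` is a required argument with no default. Trajectories
are combined by sampling each one (as a step function) onto log₁₀-year
bins of width 0.1 and summarizing the across-individual distribution
(median, quartiles).

**Heritability.** Each measure is divided by its view's body length
(L1–L3 by L4, D1–D4 by D5); H² is the raw between-strain sum of squares
over the total sum of squares of the ratio. This is deliberately the
plain SS ratio, not an expected-mean-squares variance component: with k
strains it carries the usual (k−1)/k finite-sample attenuation (≈ 0.36
recovered at a true 0.4 with six strains), which is the behavior of the
procedure it implements. Strains with a single fish are excluded with a
warning.

## Numerical and testing choices

- Internal coordinates are 0-based half-open everywhere; VCF/GFF3 convert
  at the boundary (1-based), BED is native. Half-missing genotypes are
  treated as missing.
- All stochastic functions take an explicit integer seed; msprime seeds
  are derived through `numpy.random.default_rng(seed)` and stay below
  2³¹, so identical configurations are byte-identical across runs.
- Simulation scales in the test suite (0.3–1 Mb chromosomes, 16–48
  haplotypes, 100–500 replicates) were chosen so each statistical check
  retains clear power margins at the parameter point above while the
  whole suite stays lightweight; the acceptance script uses the same
  scales with fewer replicates.
- The D-statistic calibration uses 1-Mb quartet simulations with 50-kb
  jackknife blocks (≈ 20 blocks), where the null |Z| < 3 rate and the
  f = 0.2 power are both comfortably inside their bounds.
- Known limitations: no unphased/composite LD, no XP-EHH, no genetic-map
  distances (physical bp only), no indel effects or splice-site
  annotation, no BAM/CRAM input, and the PSMC inference itself is out of
  scope (only its output is post-processed).
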