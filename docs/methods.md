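# Methods

`xopaint` analyses recombinant male X chromosomes from a bulk segregant
design in *Drosophila melanogaster*: two near-isogenic parental lines
("Hi" and "Lo", named for their locomotor-activity phenotypes) whose
X-chromosome divergence is concentrated in five SNP-dense blocks (A–E) on
a nearly homozygous background, intermated freely for 15 generations,
with males from the final generation assayed for activity and sequenced
individually. The package paints parental origin along each male X,
estimates region-wise crossover (CO) rates, tests whether CO placement is
suppressed inside SNP-dense blocks, and runs the pool-based association
statistics. A forward simulator generates truth-tagged inputs with the
design's statistical structure.

## Haplotype painting

A male X is hemizygous, so each genotype call is a haplotype observation.
Painting proceeds in three steps.

1. **Informative-site QC.** A site is informative only if every Hi
   parental sample is homozygous for one common allele, every Lo sample
   homozygous for another, and the two alleles differ. Sites flagged
   heterozygous or non-unanimous within a line are dropped and reported
   (the parental lines are ~99.9% homozygous but a few percent of
   candidate SNPs are non-fixed).
2. **Site labelling and nearest-site interpolation.** Each informative
   site is labelled Hi or Lo by allele match, Missing when uncalled, and
   Unique when the call matches neither parental allele. Missing and
   Unique sites are transparent; every base pair inherits the origin of
   the nearest labelled site by bp distance, chromosome ends inherit
   inward, and an exact midpoint between differing labels goes to the
   lower coordinate (a deterministic tie-break; breakpoints are in any
   case only localised to the interval between flanking labelled sites).
3. **Run-length smoothing.** Low-coverage single-fly sequencing leaves a
   faint background of apparently opposite parentage. A run of fewer than
   `k` consecutive opposite-origin sites flanked on both sides by the same
   origin is reassigned to the flanking origin, iterated to convergence;
   the default `k = 3` removes isolated one- and two-site discordances
   while leaving any genuine double-crossover tract spanning ≥ 3
   informative sites untouched. `k` is exposed on the CLI
   (`--smooth-k`); `k = 1` disables smoothing.

Painted origin switches are parity-limited: an even number of COs between
two informative sites leaves no switch, so painted counts are lower
bounds on true CO counts (asserted as an invariant in the tests).

## Crossover counting and rate estimation

The chromosome is segmented by sliding-window SNP density (default
100 kb windows, dense when ≥ 10 SNPs/10 kb; dense blocks at the default
design densities of 25 vs 4 SNPs/10 kb separate cleanly at this
threshold). Within dense blocks COs are counted directly as Hi↔Lo
switches, each assigned to the region containing the midpoint of its
flanking-site interval. Within a sparse gap parentage is, in the real
data, unreadable, so the analysis uses the minimum-CO inference: one CO is
inferred when the facing edges of the flanking dense blocks disagree in
painted origin (an even number of gap COs is invisible; an Unknown edge
makes the fly non-evaluable for that gap and it is dropped there only).

Rates are normalised as COs · Mb⁻¹ · fly⁻¹ · meiosis⁻¹ with the study's
denominators: 84 flies and 5 effective opportunities for a transmitted
chromatid to carry a single reciprocal CO (an X spends ~2/3 of its
history in females over 15 generations, ~10 female meioses, and half of
the chromatids carry each CO). The design actually implies ~10
female-line transmissions; both constants are exposed (`n_meioses`,
`generations`) rather than conflated, and the default follows the
published normalisation.

Uncertainty is quantified by a percentile bootstrap (default
n = 10 000) resampling **flies**, the exchangeable unit — resampling CO
events would ignore the within-fly coupling of counts. For rate ratios
the numerator and denominator counts are resampled jointly per fly.

**Exact conditional rate test.** Two Poisson rates over exposures
L₁, L₂ Mb are compared by conditioning on the total count
N = c₁ + c₂, under which c₁ ~ Binomial(N, L₁/(L₁+L₂)) when the per-Mb
rates are equal. The two-sided p-value uses the probability-mass
(minimum-likelihood) convention — the total probability of all outcomes
no more likely than the one observed — the same convention as R's
`binom.test`/`fisher.test`. This choice is pinned by the study's printed
values: on the printed counts (region C 23 COs/2.6 Mb and region D
11 COs/1.9 Mb against the 0.4 Mb gap with 10 COs) the mass method gives
p = 0.0088 and 0.0014, matching the printed 0.009 and 0.001, whereas
tail-doubling gives 0.018 and 0.0027. Both test implementations are
verified against exact-rational enumeration oracles to 10⁻¹².

## Association and parentage statistics

Per-site association between the phenotypic-extreme pools uses Fisher's
exact test on the (allele × pool) 2×2 table, probability-mass two-sided,
with flies missing a call dropped at that site only and monomorphic
sites flagged at p = 1; significance is Bonferroni at α = 0.05 over the
polymorphic sites. Per-region Hi-parentage fractions are Hi bp ÷
determinable bp (bp-weighting rather than site-weighting, so fractions
are invariant to the SNP-density profile; site-weighting is trivially
recoverable from the label matrix). Fractions are compared between pools
with the two-sided Wilcoxon rank-sum test — tie-free exact null when the
smaller pool has ≤ 25 flies, otherwise the normal approximation with tie
and continuity correction — Bonferroni-corrected over regions. The
expected-resolution arithmetic (chromosome length / 2ⁿ for n crossover
opportunities) and the ordinary least-squares fit of classical map
position (cM) on physical position (Mb) with r² complete the module.

## The simulator

The generator's defaults encode the study conditions: a 23.5 Mb X; dense
blocks C = 13.9–16.5 Mb and D = 16.9–18.8 Mb fixed by the mapping
results, and A (0.4 Mb), B (0.8 Mb), E (1.5 Mb) with published lengths
but unpublished positions placed at 3.0–3.4, 6.0–6.8 and 19.5–21.0 Mb
(package defaults, configurable, not data-derived); SNPs as an
inhomogeneous Poisson process at 25/10 kb inside blocks and 4/10 kb
outside (~0.10% genome-wide divergence); per-line heterozygous-site
flags at 7.9%/5.8%; founders 80 Hi females × 55 Lo males; 15 discrete
non-overlapping generations of random mating at population size 400 with
equal sex ratio; 788 assayed males; extreme pools of 45.

Meiosis: CO count per bivalent ~ Poisson(1.0), no interference
modelled, positions i.i.d. with piecewise-constant density weighted
1 in sparse sequence and 1/3.4 inside dense blocks (the suppression
factor under study), and each CO carried by the transmitted chromatid
with probability 1/2. Males transmit their X intact to daughters only;
sons receive the maternal gamete.

Phenotype: activity = baseline + Σ effect · HiFraction(region) + Gaussian
noise, floored at 0, with effects in C and D split 70%/30%
(875 and 375 counts/day per unit Hi fraction, baseline 310, sd 110).
The split follows the stronger association observed in C; the scale was
calibrated once so that the extreme pools land in the low-hundreds vs
mid-thousands counts/day regime of the study (pool means ≈ 194 and
≈ 1 609 counts/day there; ≈ 140 and ≈ 1 720 in the simulation at seed 1).
Genotyping noise is per-site dropout (default 0.15, mimicking ~4–6 M
reads per fly) and allele flips (default 0.005, standing in for
sequencing error and any non-CO gene conversion, which is deliberately
not modelled separately since the study could not distinguish the two).

All randomness flows from a single seed through
`numpy.random.SeedSequence` spawns; every operation is bit-for-bit
reproducible given (config, seed).

### What the generator does and does not emulate

It reproduces the design's sampling structure: clustered divergence,
female-only recombination with dense-block suppression, pedigree sharing
from a closed population, pool selection, and call-level noise. It does
not model crossover interference, gene conversion, non-random mating,
overlapping generations, viability selection, or read-level error
profiles. Two consequences matter for interpreting the tests:

- **Origin-switch visibility.** A CO changes parentage only if the
  mother is heterozygous Hi/Lo at the breakpoint. With founder X
  frequencies 160:55 the population heterozygosity equilibrates near
  0.38, so only ~40% of realised COs are visible as switches; the real
  study's per-region counts are ~2–3× larger than the simulator's at
  the same nominal CO rate, consistent with its effective meiosis count
  being larger than the published denominator of 5.
- **Pedigree variance.** After 15 generations at population size 400,
  the 84 analysed X's share deep ancestry: region-wise visible-CO counts
  are dominated by the drift of a modest number of ancestral
  breakpoints' copy numbers. A fly-resampling bootstrap cannot see this
  across-population variance component, so the 95% CI of the
  sparse:dense rate-ratio covers the generating value 3.4 in only ~70%
  of replicate populations (quantified in the test suite); the same
  pedigree structure leaves megabase-scale linkage-disequilibrium
  shoulders around the causal blocks, so a substantial minority of
  Bonferroni-significant association sites fall in the sparse flanks of
  C and D rather than inside them. Both are properties of the design
  being simulated, not of the estimators, and are reported as measured.

The rate-estimation checks use a random 84-male analysis cohort (the
study's QC-passing count) rather than the phenotypic extremes: under the
additive region-fraction phenotype model the extremes are strongly
depleted of crossovers in and around the causal blocks, often leaving
the gap count at zero. The study itself noted that selection for
matching parentage in C and D depresses the sparse-gap estimate.

## Numerical choices and degenerate inputs

- Coordinates are 0-based half-open internally, 1-based in VCF.
- Both counts zero in the rate test → p = 1 by convention.
- Probability-mass tie comparisons use a 1 + 10⁻⁷ relative guard
  against float ties (the convention of the reference implementations).
- An entirely Unknown region is excluded from fraction and gap
  statistics and logged, never silently zeroed.
- All-equal activities split into pools deterministically by fly id.
- Problem sizes in the shipped tests (chosen for a laptop-scale run):
  parameter recovery uses 50 replicate populations with 84-fly analysis
  cohorts and 4 000 bootstrap resamples; bootstrap calibration uses 500
  Poisson replicates; association localisation aggregates 3 replicate
  studies of 788 males.
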