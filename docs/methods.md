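# Methods

This note documents the models implemented in `introhmm`, the choices made
where the design was genuinely open, and what the validation does and does
not demonstrate.

## Marker selection

The HMM observes species-informative SNPs only.  A site is a marker for
one direction of introgression when, on called genotypes: every donor
individual and at least one recipient individual is genotyped; the donor
population is monomorphic; the donor-allele frequency difference between
the populations is at least `min_freq_diff` (default 0.30 — below that,
low-frequency neutral variation in the recipient swamps the signal); and
at most `max_het_fraction` (default 0.80) of all genotyped individuals at
the site are heterozygous (an excess of heterozygotes indicates mapping
error).  Monomorphism is evaluated on called genotypes; a missing donor
call excludes the site through the completeness rule rather than being
ignored.  Coverage filtering is applied upstream of selection: per
individual, calls are masked where total depth is below 5 or above that
individual's genome-wide 99th-percentile depth (numpy's
linear-interpolation quantile estimator, computed over all of the
individual's called sites).  Coordinates are 1-based inclusive throughout
(VCF convention).

## The six-state HMM

States: `homo_r`, `het`, `homo_d` and one error twin for each.  Error
states exist because real alignments contain stretches of aberrant signal
(collapsed repeats, misassembly) that would otherwise be parsed as rapid
ancestry switching; they emit exactly like their non-error counterpart and
differ only in transition dynamics, so an aberrant stretch is absorbed at
low cost and later resolved by the tract filters.

**Transitions.**  For a marker gap of `d` bp, base switch probabilities
are `a = c·d·exp(−c·d)` and `a_e = m·c·d·exp(−m·c·d)` with defaults
`c = 1e-9` per bp per generation and `m = 25,000`.  The full 6×6 matrix
(rows = from-state, order `homo_r, het, homo_d, homo_r_e, het_e,
homo_d_e`):

* non-error rows: `1−4a` on the diagonal, `a` to each of the four
  reachable states, 0 to the state's own error twin;
* error rows: 0 to the own non-error twin, `(1−2a_e)/4` to each of the
  two reachable non-error states, `2a_e` on the diagonal, and the
  remaining `(1−2a_e)/2` split between the other two error states —
  evenly from `homo_r_e`, and 9:1 in favour of `homo_r_e` from `het_e`
  and `homo_d_e` (errors resolve toward the common recipient-like
  background).

Every row sums to 1 exactly; construction fails loudly if `4a > 1` (which
cannot occur for realistic `c` and marker spacing, since `a ≤ 1/e`).
Forbidding direct transitions between emission-identical twins keeps the
state pair identifiable.  The 9:1 asymmetry and the recipient-heavy
initial distribution are deliberate asymmetries: they (and only they)
break the otherwise exact symmetry under swapping donor/recipient allele
roles, which the test suite verifies by symmetrising them.

**Emissions.**  The donor-allele read count `k` out of coverage `n` is a
binomial draw of true fragments (donor probability `p` = 0, ½, 1 by
genotype) followed by independent per-read miscalls with probability
`p_ab`.  The double sum is evaluated in log space on a vectorised (i, j)
grid, exact to float precision; distributions are cached per
`(n, p, p_ab)`, so decoding costs one table lookup per marker.  A missing
observation (`n = 0`) emits 1 in every state.  `p_ab` defaults to 0.005,
a typical short-read per-base error rate; it is configurable and the
simulation uses the same value it decodes with.

**Decoding.**  Scaled forward–backward per (individual, chromosome);
chromosome boundaries reset the chain.  The initial distribution defaults
to 0.995 on `homo_r` and 0.001 elsewhere — genome-wide introgression is
well under 1% in the systems this targets, and with 10⁵–10⁶ markers per
chromosome the prior is quickly overwhelmed anyway.  Per-marker posteriors
are exact (validated against full path enumeration on short chains to
1e-10); the most probable state per marker, not a Viterbi path, defines
tracts.  Individuals sharing a marker grid are decoded in one batched scan.

## Tract construction and filtering

Runs of identical most-probable states become tracts; a tract spans its
first to last marker position inclusive (marker-bounded spans are
conservative and reproducible; extending spans midway to flanking markers
would be equally defensible but is not done).  A marker is an
"introgression SNP" when its posterior mass on `het` + `homo_d` is
≥ 0.5.

Seven ordered filters then clean the raw tracts: (1) adjacent `het` /
`homo_d` tracts merge, label by the larger per-label introgression-SNP
sum, ties to `het`; (2) an introgression tract with < 15 introgression
SNPs whose count divided by the total SNPs of the error runs immediately
left and right is < 3 is demoted to its error twin (no adjacent error run:
filter does not apply); (3) error runs bounded on both sides by `homo_r`
become `homo_r`; (4) error runs bounded on both sides by introgression
tracts merge with both flanks, label by introgression-SNP majority;
(5) remaining error tracts become `homo_r`; (6) a `homo_r` tract with
< 5 total SNPs flanked by introgression tracts of ≥ 10 total SNPs each
merges with both flanks, label by total-SNP majority ("total" read
literally); (7) filter 1 re-runs.  Adjacent same-label tracts coalesce
after every step, and filters 4 and 6 iterate to a fixed point so the
whole cascade is idempotent (property-tested on randomized fixtures).
"Adjacent" always means consecutive in the ordered per-chromosome list —
tracts partition the marker sequence, so no base-pair gap criterion is
needed.

Reported introgressions are `het`/`homo_d` tracts spanning ≥ 500 bp with
≥ 10 introgression SNPs and ≤ 30% of their span inside annotated repeats
(rule skipped with a warning when no repeat annotation is supplied).
Overlapping reported tracts across lines merge single-linkage into
regions; breakpoints at every member endpoint decompose a region into
blocks annotated with member sets, and region frequency is distinct
members over lines assayed.

## Validation simulator

The generator reproduces the validation protocol's study conditions:
introgression sizes from a configurable list, inter-tract spacing uniform
on 25–75 kb, each tract heterozygous or homozygous with probability 0.5,
coverage uniform on {10..25}, binomial read sampling from the two
haplotypes, and independent per-read miscalls at `p_ab`.  Two density
presets mirror the real marker spacings: `yak/san-like` (one fixed
difference per 130 bp) and `yak/tei-like` (one per 55 bp), each with
polymorphic noise sites at a tenth of that density (half segregating in
the recipient, half breaking donor monomorphism; polymorphic allele
frequencies uniform on [0.1, 0.9] — a flat compromise in the absence of a
stated spectrum).  Alleles inside introgressions are drawn from donor
population frequencies, elsewhere from recipient frequencies, so shared
polymorphism produces realistic marker noise.  All draws come from one
seeded generator per individual in documented order; outputs are
bit-reproducible.

A truth interval counts as detected when any called introgression tract
overlaps it (a minimum-reciprocal-overlap criterion is available); false
positives are called tracts overlapping no truth interval, reported both
as full tract length and as called length outside all truth intervals.

What the simulator does *not* emulate: linkage disequilibrium within
populations, coverage autocorrelation, indels and genotyping error beyond
per-read miscalls, repeats, and selection.  Passing benchmarks therefore
demonstrate the statistical machinery under the stated noise model, not
performance on any particular real alignment pipeline.

## Benchmark scale

The acceptance benchmark uses 30 Mb genomes (3 × 10 Mb chromosomes) and
three admixed individuals per regime, which yields 240+ introgressions
per size class — enough that a 10% false-negative rate would be estimated
with a standard error near 2%.  Homozygous runs use size classes
{4, 10, 50, 100} kb; heterozygous runs {3, 10, 50, 100} kb.

## ABBA–BABA statistics

Site contributions use population allele frequencies:
`ABBA = (1−p1)p2p3(1−p4)`, `BABA = p1(1−p2)p3(1−p4)`;
`D = Σ(ABBA−BABA)/Σ(ABBA+BABA)`.  Sites where the outgroup is
majority-derived are repolarised; intermediate outgroup frequencies are
retained (the frequency weighting handles them).  `f_d` normalises the D
numerator by its value under complete introgression, giving the donor
role at each site to whichever of P2/P3 has the higher derived frequency;
it is computed genome-wide.  Standard errors come from a weighted
delete-one-block jackknife over 100 kb windows with Busing-style
weighting by block site count (the exact weighting of the original
analysis is unstated; this is the standard choice).  Degenerate SE = 0
cases are flagged rather than producing infinite Z.

## Permutation tests

The X test compares the observed length-weighted fraction of introgressed
material on the X with a null in which every tract is independently
assigned to the X with probability 0.1841 (the X share of the assembly);
the one-sided p-value counts replicates strictly below the observed
fraction.  Cumulative length (not tract count) is the test statistic.

The enrichment test partitions the genome into eight categories by the
hierarchy CDS > exon > 5′ UTR > 3′ UTR > intron > 2 kb upstream
(strand-aware) > within-10 kb intergenic > intergenic, painting low to
high priority so every base has exactly one label.  Observed enrichment
per category is the introgressed percentage over the genomic percentage;
the null relocates each block size-preserved to a uniform position
(chromosome chosen proportional to its number of valid start positions),
and p-values are two-sided by doubling the smaller empirical tail.

## Ancestral-variation expectations

Closed forms: `T_fixed = −4Ne(1−p)ln(1−p)/p`, `T_lost = −4Ne·p·ln(p)/(1−p)`
generations (the two are mirror images under p → 1−p); divergence dating
scales a pair's synonymous divergence against the melanogaster/simulans
calibration (Ks 0.1219 = 3 MY); generations elapsed use 365.25 days per
year (365 gives the same values at three significant figures).  Expected
surviving ancestral fragment lengths are sampled as the sum of two
one-sided genetic distances to the nearest recombination event divided by
`r = 1.2e-8` per bp.  The one-sided distance density is injected as a
function; the default — exponential with rate equal to the elapsed
generations per morgan — is an approximation to the full
ancestral-recombination density and is labelled as such, so the exact
12/19/24 bp quantile reproduction of the original supplementary panels is
out of scope.

## Known limitations

* Error-row cross-transition weights (the 9:1 split) are structural
  constants, not fitted; they matter only in pathological regions.
* No Baum–Welch parameter estimation: `c`, `m`, `p_ab` are user
  parameters.
* The caller treats chromosomes independently and assumes sorted,
  biallelic input; indels and multi-allelic sites are dropped at load
  time.
* `f_d` inherits its known downward bias under post-divergence drift;
  the tests bound it rather than correcting it.
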