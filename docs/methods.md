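# Methods

## Cut-site geometry and verification

An enzyme is described by an IUPAC recognition sequence of length *L* and a
cut offset *c* (bases 5′ of the cleavage point on the sense strand; the
caret in `C^CGG` gives c = 1). Cleavage inside an occurrence spanning
[s, s+L−1] releases a downstream fragment whose forward-strand read starts
at s + c and an upstream fragment whose reverse-strand read has its 5′ end
at s + L − c − 1. Verification inverts this: a forward event at p implies
the window starting at p − c, a reverse event the window starting at
p − L + c + 1, and the row is kept only if the reference sequence over that
window IUPAC-matches the recognition sequence (its reverse complement for
reverse events — identical for the palindromic enzymes shipped as presets:
MspI `C^CGG`, ApeKI `G^CWGC`, EcoRI `G^AATTC`; ApeKI's cut position is
usually quoted without a caret, and the preset assumes the standard
`G^CWGC`). Windows that fall outside the contig are rejected, not errors.

Matching rules: the reference is uppercased before matching (soft-masking
marks repeats, not different bases), and an `N` in the *reference* matches
only the fully degenerate pattern letter `N` — a window overlapping an
assembly gap cannot be verified and must not pass the filter. Coordinates
are 1-based inclusive throughout (SAM convention); BED output is 0-based
half-open. Enzymes whose cleavage point lies outside the recognition
sequence (type IIS) are out of scope.

Read filtering defaults are permissive, mirroring how cut-site counting is
usually run: primary, mapped, non-supplementary, non-QC-fail,
non-duplicate alignments at any MAPQ. MAPQ threshold, duplicate handling, a
first-in-pair restriction for paired data, and a maximum 5′ soft-clip are
exposed as options; the aligned end is always used for the 5′ position
(clipped bases ignored), since a clipped or shifted start fails window
verification anyway.

## Count model and differential testing

Counts at verified cut sites are modelled as negative binomial,
Var(y) = μ + φμ². The per-sample goodness-of-fit check fits (size, mean) by
maximum likelihood (the ML mean is the sample mean; the size is profiled
numerically) and computes a Pearson chi-square over count categories with
both boundary cells pooled until every expected frequency is ≥ 5, on
categories − 3 degrees of freedom. Pooling at both ends matters: with
ML-fitted parameters, unpooled near-zero-expectation cells destroy the null
distribution of the statistic; the implementation's null p-values are
verified to be uniform by simulation.

**Filtering.** Sites with CPM > 1 in at least *k* samples are kept, with
*k* defaulting to the size of the smallest group — weaker sites carry no
power and inflate the multiple-testing burden.

**Normalization.** Trimmed mean of M-values. The reference sample is the
one whose 75th-percentile count fraction is closest to the mean of those
fractions. For each other sample, over sites positive in both it and the
reference, M = log2 ratio of count fractions and A = mean log2 abundance
are computed; the 30% most extreme M and 5% most extreme A are trimmed
two-sidedly, and the factor is 2 to the variance-weighted mean of the
remaining M (delta-method binomial weights 1/n<sub>s</sub> − 1/N<sub>s</sub> +
1/n<sub>r</sub> − 1/N<sub>r</sub>). Factors are rescaled to geometric mean 1.
A library-size-only option (`normalization="libsize"`) is available. Note
one subtlety: rescaling a single sample by a constant leaves fractions, M
values and trimming unchanged but shrinks that sample's precision weights,
so factors are only *nearly* invariant — this matches the reference TMM
implementation and is covered by a tolerance in the tests.

**Dispersion.** The common dispersion maximizes the summed Cox–Reid
adjusted profile likelihood APL<sub>g</sub>(φ) = ℓ<sub>g</sub>(β̂; φ) − ½ log
det(XᵀWX), with Fisher weights W = μ/(1 + φμ); the adjustment removes the
downward bias of plain profile likelihood in small samples. Tagwise values
maximize APL<sub>g</sub>(φ) + (prior_df / residual_df) · mean APL(φ),
shrinking each site toward the common value; prior_df defaults to 10 and no
abundance trend is fitted (trend estimation is out of scope). Tagwise
maxima are located on a 21-point log2 grid spanning 2<sup>±6</sup> around
the common value with quadratic interpolation at the grid maximum.

**Two-group exact test.** Counts are first rescaled deterministically to
the geometric-mean effective library size (an acknowledged expected-value
approximation of quantile-adjusted conditional ML). Conditional on the
rounded total t of a site, the group sums are NB with means proportional to
the group sizes and group-sum dispersion φ/n<sub>g</sub>; the two-sided
p-value sums the probabilities of all splits no more likely than the
observed one (minimum-likelihood rule, standard for discrete conditional
tests and brute-force checkable). φ = 0 degenerates to the conditional
binomial test. The discrete null makes the test conservative, which the
tests assert.

**GLM likelihood-ratio test.** Per site, a log-link NB GLM with offset
log(effective library size) is fitted by Fisher-scoring IRLS (at most 50
iterations, convergence on relative deviance change < 1e−8, step-halving on
deviance increase, no ridge term) under the full design (intercept +
optional block dummies + group indicator) and the null design without the
group column; 2(ℓ_full − ℓ_null) is referred to chi-square with the number
of dropped coefficients as degrees of freedom. Non-converged sites are
reported with p = NaN rather than a silently wrong value, and NaNs are
excluded from the Benjamini–Hochberg adjustment (step-up, capped at 1,
mapped back to input order).

`diff_meth` chooses the exact test for plain two-group designs and the GLM
for designs with a blocking factor; both can be forced. The implementation
of TMM, the exact test and the GLM were cross-checked during development
against an independent reference implementation on fixed matrices, and
those values are frozen into the test suite (agreement ~1e−9 for TMM, 1e−8
for exact-test p-values, 1e−6 for GLM p-values and log-fold-changes).

## QC

Per sample: library size (column total) and number of sites with ≥ 1 read,
plotted against each other and coloured by group — failed digests and thin
libraries separate visually; no automatic outlier threshold is imposed.
PCA operates on log2(CPM + 0.5) (the 0.5 prior avoids log 0), drops
zero-variance sites, centres each site and takes sample scores from the
SVD; variance-explained fractions are non-increasing and sum to ≤ 1.

## The simulator

`simulate_genome` draws a uniform ACGT background, plants the requested
number of recognition occurrences at jittered, evenly spaced positions (at
least twice the read length apart, with margins so every read fits inside
the contig), realizes degenerate pattern letters uniformly, and then
mutates away any spurious match of the recognition sequence or its reverse
complement — so the in-silico digest of the emitted genome returns exactly
the planted occurrences and count-recovery oracles are exact, not
approximate. `simulate_experiment` draws per-site baseline abundances from
a log-normal (sd 1 on the log scale, a typical dynamic range for digest
libraries), multiplies or divides the group-2 means of planted
differential sites by the effect fold (half each way), draws per-sample
counts as NB(depth-scaled mean, φ), and emits each read as a full-match
alignment anchored at the cut (50:50 forward/reverse, exercising both
strand branches of the window geometry). A configurable fraction of reads
is displaced to uniform positions away from every occurrence; such reads
can never verify, so the planted mis-map fraction is recovered as the
rejected-read fraction. All randomness flows from one seeded generator;
outputs are bit-reproducible and the configuration is recorded in the BAM
header.

Default study conditions: 100 kb genome, 200 sites, two groups of six
samples, 20 000 reads per sample (~100 reads per site), dispersion 0.1,
10% differential sites at 4-fold, no mis-mapping, 75 bp reads. The
count-level generator also supports litter/block structure: blocks of three
samples allocated unevenly to the two conditions (3+0, 2+1, 1+2, 0+3, …)
with a per-(site, block) log-normal effect, so ignoring the block leaks
shared within-litter variation into the group contrast — modelling the
block restores nominal type-I error, omitting it inflates it, which the
tests assert.

What the simulator does *not* emulate: sequencing errors and base-quality
variation, adapter read-through, partial digestion kinetics, fragment-size
selection, copy-number variation, or an explicit per-allele methylation
state (methylation enters only through the per-site mean). Passing tests
therefore demonstrate correctness of the counting, verification and
inference machinery under the stated count model — not robustness to
alignment artefacts beyond uniform mis-placement.

## Problem sizes and numerical choices

Simulation-based checks run at sizes chosen to keep the full suite fast on
a laptop while leaving negligible Monte-Carlo error: 50 random genomes of
3–8 kb for the verification oracle, 10⁵ reads per sample for the mis-map
fraction (binomial sd ≈ 0.001 around 0.1), 1000 sites × 12 samples for
null calibration, 10 seeds × 500 sites for power/FDP, and 20 seeds × 500
sites for dispersion recovery. Ties in nearest-gene annotation go to the
gene with the smaller start, then the lexicographically smaller id;
distance is strand-agnostic and 0 inside the gene body. Degenerate inputs
fail loudly: unsorted or unindexed BAMs, contig mismatches, saturated
designs, all-constant count vectors and out-of-range p-values are errors,
not warnings.

## Known limitations

- Only cut sites inside the recognition sequence are modelled (no type IIS
  enzymes, nickases, or star activity).
- No quasi-likelihood F-test, abundance-trended dispersion, or region-level
  (DMR) aggregation; the unit of inference is the single cut site (or the
  strand-collapsed occurrence).
- The exact test's library equalization is an expected-value approximation;
  for strongly unequal library sizes the GLM route is preferable.
- GO/pathway enrichment is out of scope; the annotation step stops at the
  nearest gene.
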