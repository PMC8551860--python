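# Methods

## The design being modelled

A NAM population is built by crossing a panel of wild donors to one
recurrent elite parent, backcrossing the F1 to the elite parent once, and
advancing lines three generations by single-seed descent. Each resulting
line is expected to be heterozygous at 6.25% of the markers segregating in
its family (71.875% elite-homozygous, 21.875% wild-homozygous). The lines
are genotyped as single plants at this stage, then maintained for five
further seasons by plot propagation: a plot is sown from seeds of the
previous season's harvested ears, a fixed number of ears is harvested, and
their seeds sow the next season. Finally, DNA of 12 seedlings per line is
pooled and genotyped once more. Heterozygosity that survived propagation
shows up as a heterozygous pooled call ("reconstructed heterozygosity");
loci where one allele took over show up as homozygous calls.

## Fixation statistics

Only entries heterozygous in the base generation are informative. They are
recoded as fixation values (−1 elite-fixed / 0 still segregating / +1
wild-fixed / missing), and per SNP

    AFR = (n_elite + n_wild) / n_het0        (fixation rate)
    RFD = (n_wild − n_elite) / n_het0        (fixation direction)

By default missing later calls stay in the denominator (the rates are
defined against the base-generation heterozygote count); an
"observed"-denominator mode divides by the non-missing entries instead.
SNPs with fewer than 10 initially heterozygous lines are excluded from the
scan — rates estimated from a handful of lines are dominated by noise.

The selection scan sums elite- and wild-fixed counts over sliding windows
of 10 consecutive SNPs (step 1, never crossing a chromosome boundary;
chromosomes with fewer SNPs than the window yield none) and tests the
summed counts against a 1:1 ratio with the plain chi-square
goodness-of-fit statistic on 1 df, without continuity correction. Windows
with zero fixed counts are untestable and are excluded from the Bonferroni
denominator; significance is declared at p < α / n_testable with α = 0.01.
Ties in map position are broken by SNP identifier, so window membership is
deterministic.

**Caveat — correlated counts.** The window statistic treats the summed
counts as independent observations. They are not: a line heterozygous
across a segment of linked SNPs fixes that whole segment in one direction
as a single event, so window counts are positively correlated and the
nominal chi-square null is anti-conservative. Tolerance-based pooled
calling amplifies this: a single one-sided pool produces same-direction
"fixed" calls across the line's whole heterozygous segment. In neutral
simulations at 500 lines × 2,000 SNPs the Bonferroni-significant window
fraction is essentially zero under exact calling of the whole final
cohort, but averages a few percent under 12-plant tolerance calling. The
scan is therefore best read as a ranking of candidate regions, with the
genome-wide background (and the pooled-calling analysis below) as the
yardstick — single marginally significant windows should not be
over-interpreted.

## Analytic selfing expectations

Selfing halves the heterozygote fraction per generation and fixes a
quarter of it in each homozygous class; after n generations a locus with
initial class probabilities (a, h, b) reaches
(a + h(1−2⁻ⁿ)/2, h·2⁻ⁿ, b + h(1−2⁻ⁿ)/2). This closed form composes over
generations and is exact; it provides the expectations against which both
the simulator and the pooled-sampling analysis are checked.

## Pooled-sampling bias

A pooled call is modelled by its count abstraction: `pool_n` plants drawn
independently, each in one focal homozygous class with probability
`p_seg`; the pool triggers a homozygous call for that class when at least
`k_threshold` plants belong to it. The probability is the binomial upper
tail; the Monte-Carlo estimator (default 10⁶ trials, standard error
√(p̂(1−p̂)/n)) mirrors the physical sampling experiment and is verified
against the closed form. Two thresholds matter in practice: all 12 of 12
(a strict caller) and ≥9 of 12, the count analogue of a caller that
tolerates ~20% of the opposite allele in the fluorescence signal. One
class is reported per call; callers symmetrise over the two homozygous
classes, which avoids double counting when `p_seg` ≠ ½. Fluorescence
physics is deliberately out of scope — only the count threshold is
modelled.

## The forward simulator

*Founders.* The elite parent is homozygous for the elite allele
everywhere. Each wild donor is fully inbred and carries the wild allele at
an independent random subset of markers (`wild_polymorphism_rate`, default
0.55 — a typical fraction of array markers segregating between one donor
and the elite parent in such populations), so families segregate at
different marker subsets.

*Recombination.* Crossovers follow the Haldane model: per chromosome a
Poisson number with mean L/100 (L = marker span in cM), uniform positions,
no interference. The batch generator uses the equivalent Markov chain
along the marker skeleton — the source haplotype switches between adjacent
markers with probability r = (1 − e^(−2d/100))/2 — which is the exact
marginal of the crossover process at the markers; a test checks the two
routes agree. Because the process is Markov, lines are propagated on the
subset of loci still segregating in them (with Haldane fractions of the
subset distances) and re-expanded afterwards; this is exact and makes the
default scales run in seconds.

*Propagation.* Each season sows `n_sown` selfed seeds of the previous
season's harvested mothers (seeds pick mothers uniformly — ears yield many
more seeds than are sown, so sowing is a multinomial draw over mothers).
Per-locus fitness is multiplicative, (1, 1 + hs, 1 + s) for (elite hom,
het, wild hom), and acts in one of two phases: **viability** weights which
sown seeds establish (implemented by rejection sampling against the
maximal attainable weight, i.e. exact viability selection), **harvest**
weights which `n_ears` plants are chosen (without replacement) as mothers.
The default schedule sows 60, 60, 60, 100 and finally 20 plants,
harvesting 20 ears per season; the first-season plot size is not dictated
by the design and defaults to 60 like the following seasons. One harvested
ear corresponds to one mother plant.

*Pooled calling.* 12 of the final 20 plants are sampled without
replacement; per marker, if the minor-allele fraction among the 24 allele
copies is ≤ `minor_tolerance` (default 0.2) the majority homozygote is
called, otherwise the call is heterozygous; calls fail independently at
`failure_rate` (default 0.01, a realistic array no-call rate). The base
generation is called perfectly from the single genotyped plant, matching
the design. All randomness descends from one seed via spawned
sub-streams, so identical configurations give byte-identical outputs.

*What the simulator does not model.* Mutation, outcrossing, seed
dormancy, shared ancestry between donor accessions, environment-dependent
phenology, and fluorescence-level calling artifacts (including the
cluster-file effects that can depress heterozygous calls array-wide).
Passing tests on simulated data therefore validate the statistical
machinery and its null behaviour, not the biology of any particular real
population.

## Quality control

Markers are retained when (a) at least one family shows two distinct
non-missing genotype classes, (b) the missing fraction over all lines is
< 10%, and (c) the heterozygous fraction is < 12.5% (twice the base-
generation expectation). Thresholds are strict inequalities; the het-rate
denominator is the non-missing calls (missingness is rule (b)'s job). The
rules are applied to each generation's matrix separately and the retained
sets intersected. Markers with identical call vectors (including the
missingness pattern) are collapsed to the first in map order. Lines are
dropped when more than 5% (configurable) of their base-homozygous markers
show the *opposite* homozygote later — a transition selfing cannot
produce, indicating a sample mix-up; the denominator is all base-
homozygous markers, since a missing later call cannot be a mismatch. All
rules are computed on the input matrix, so the filters are idempotent and
order-independent.

## Trait-effect association

Per-SNP wild-allele effects are ordinary least-squares slopes of line
trait values on wild-allele dosage (0/1/2) over complete pairs, intercept
fitted, estimated on all lines with data; markers with constant dosage or
fewer than 3 pairs get no estimate. An optional mode centres trait and
dosage within families first. The Pearson correlation between effects and
RFD, over markers with both values, asks whether trait-moving alleles were
preferentially fixed. No kinship or multiple-testing machinery is layered
on top — the estimator is deliberately the simple linear model.

## Problem sizes and numerical choices

The test suite exercises the neutral null at 500 lines × 2,000 SNPs and
locus recovery with 100 replicates of 250 lines × 150 SNPs (5 families,
donors polymorphic everywhere, ≈15 initially heterozygous lines per SNP) —
population sizes at which the window scan has clear power for s = 1 while
a full run of the suite stays in the low minutes. Monte-Carlo checks use
3-standard-error bands around their analytic expectations; null-fraction
checks cluster standard errors by line, since lines (not SNPs) are the
independent units. Probability triples must sum to 1 within 1e-9;
degenerate inputs (empty maps, zero-heterozygote SNPs, empty windows)
return missing values or raise, as documented per function.
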