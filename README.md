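# fixscan

Selection scans from **temporal heterozygosity** in backcross-derived
nested association mapping (NAM) populations.

When a plant population with residual heterozygosity is maintained by
selfing and field propagation, every initially heterozygous locus is a
little natural experiment: with no selection its two alleles should fix in
later generations at equal rates, so any *directional* excess of one
allele among the fixed lines is a footprint of natural or artificial
selection during propagation. `fixscan` implements the full analysis for
the standard design — lines genotyped once as single plants (one
backcross + three selfings, "BC1S3") and again several seasons later from
pooled DNA of their progeny — plus the analytic and simulation machinery
needed to interpret it.

## The statistics

For each SNP, over the lines that were heterozygous in the base
generation, the later pooled call is recoded as a **fixation value**: −1
(fixed for the elite allele), 0 (still heterozygous — both alleles present
in the pool, "reconstructed heterozygosity"), +1 (fixed for the wild
allele). Per SNP,

- **AFR** (allele fixation rate) = (n₋₁ + n₊₁) / n_het0 ∈ [0, 1] — how much
  initial heterozygosity was lost;
- **RFD** (relative fixation direction) = (n₊₁ − n₋₁) / n_het0 ∈ [−1, 1] —
  which allele it was lost to (positive = wild).

Deviations from symmetric fixation are tested in sliding windows of 10
consecutive SNPs: the summed elite/wild fixed counts are compared to a 1:1
ratio with a chi-square goodness-of-fit test,
χ² = (n_elite − n_wild)² / (n_elite + n_wild) on 1 df, Bonferroni-corrected
over all testable windows at α = 0.01.

Two neutral baselines support interpretation:

- an **analytic selfing model** — per selfing generation the heterozygote
  fraction halves and each homozygous class gains a quarter of it, so a
  BC1 line reaches 71.875% / 6.25% / 21.875% after three selfings and a
  heterozygous locus reaches 0.484375 / 0.03125 / 0.484375 after five more;
- a **pooled-sampling bias simulation** — the probability that a pool of
  12 plants accidentally triggers a homozygous call (all 12, or ≥9 under a
  ~20% calling tolerance), estimated by binomial Monte-Carlo and verified
  against the exact binomial tail.

A forward **simulator** generates complete ground-truthed inputs: founder
crosses, backcross + single-seed-descent selfing, multi-season plot
propagation with optional per-locus viability or harvest selection,
12-plant DNA pooling and tolerance-based allele calling.

## Worked example

`examples/simulate_and_scan.py` simulates 250 lines × 150 SNPs with one
viability-selected wild locus (s = 1) and scans for it:

```
simulated 250 lines x 150 SNPs; selected locus: 1H_00076 (wild allele favoured)
scan kept 149 informative SNPs (>=10 initially heterozygous lines)
mean AFR 0.260, mean RFD +0.143

62 of 140 windows significant (Bonferroni-corrected p < 0.01); the 8 strongest:
start_snp  end_snp  n_elite  n_wild  chi2        p  mean_rfd
 1H_00071 1H_00080        0     140   140 2.66e-32     0.805
 1H_00070 1H_00079        2     144   138  6.9e-32     0.778
 1H_00072 1H_00081        0     135   135  3.3e-31     0.806
 ...
```

The strongest window sits directly on the selected locus; its positive
mean RFD identifies the wild allele as the favoured one. The other
examples cover the analytic selfing expectations, the pooled-sampling
bias grid, and trait-effect association (`rfd_effect_correlation`), each
printing the numbers it computes and what they mean.

A thin CLI wraps the same library:

```sh
fixscan simulate --n-snps 500 --seed 1 --out-prefix run
fixscan fixate --g0 run.g0.tsv --g8 run.g8.tsv --map run.map.tsv --out-prefix scan
fixscan expect --selfings 5 --seed 1 --out bias_grid.tsv
```

Inputs are plain TSV (genotype matrices coded A/H/B/NA, a genetic map
`snp`/`chrom`/`cm`, long trait tables); biallelic VCF can be imported.
See `docs/methods.md` for the model, parameter defaults and limitations.

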