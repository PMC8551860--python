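"""Simulate a backcross NAM population with one selected locus and find it.

A 5-family population is pushed through five seasons of plot propagation.
One locus carries viability selection favouring the wild allele (s = 1:
wild homozygotes establish twice as often as elite homozygotes). The scan
recodes initially heterozygous loci as fixation values, computes per-SNP
AFR/RFD and tests 10-SNP windows against symmetric (1:1) fixation.
"""

import fixscan as fx

gmap = fx.make_genetic_map(150, chromosomes=("1H",), length_cm=150.0)
target = gmap["snp"].iloc[75]
selection = fx.SelectionModel(
    (fx.SelectedLocus(snp=target, s=1.0, h=0.5, phase="viability"),)
)
config = fx.ExperimentConfig(
    gmap=gmap, n_families=5, lines_per_family=50, wild_polymorphism_rate=1.0,
    selection=selection, seed=7,
)
result = fx.simulate_experiment(config)
print(f"simulated {result.log['n_lines']} lines x {result.log['n_snps']} SNPs; "
      f"selected locus: {target} (wild allele favoured)")

scan = fx.run_scan(result.g0, result.g8)
print(f"scan kept {len(scan.summaries)} informative SNPs "
      f"(>=10 initially heterozygous lines)")
print(f"mean AFR {scan.summaries['afr'].mean():.3f}, "
      f"mean RFD {scan.summaries['rfd'].mean():+.3f}")

sig = scan.windows[scan.windows["significant"]]
print(f"\n{len(sig)} of {scan.log['n_testable_windows']} windows significant "
      f"(Bonferroni-corrected p < 0.01); the 8 strongest:")
cols = ["start_snp", "end_snp", "n_elite", "n_wild", "chi2", "p", "mean_rfd"]
top = sig.sort_values("chi2", ascending=False).head(8)
print(top[cols].to_string(index=False, float_format=lambda v: f"{v:.3g}"))
print(
    "\nThe strongest window sits directly on the selected locus and the"
    "\nrest shoulder it (linked hitchhiking); their positive mean RFD says"
    "\nthe wild allele was fixed preferentially, matching the ground truth."
)
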