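"""Genotype-class proportions under backcrossing and repeated selfing.

Each selfing generation halves the heterozygote fraction and fixes a
quarter of it in each homozygous class. Starting from the BC1 distribution
(half elite-homozygous, half heterozygous) this yields the expected makeup
of a backcross line after three selfings, and starting from a pure
heterozygote it yields the residual segregation after five more seasons.
"""

from fixscan import BC1_TRIPLE, F1_TRIPLE, selfing_segregation

bc1s3 = selfing_segregation(BC1_TRIPLE, 3)
print("BC1 + 3 selfings (the genotyped base generation):")
print(f"  elite-homozygous {bc1s3.p_hom_elite:.5%}")
print(f"  heterozygous     {bc1s3.p_het:.5%}")
print(f"  wild-homozygous  {bc1s3.p_hom_wild:.5%}")

for n in (1, 5):
    t = selfing_segregation(F1_TRIPLE, n)
    print(f"\nheterozygous locus after {n} selfing generation(s):")
    print(f"  {t.p_hom_elite:.6g} : {t.p_het:.6g} : {t.p_hom_wild:.6g}")

print(
    "\nThe five-generation residual (3.125% heterozygotes, 48.4375% per"
    "\nhomozygous class) is the neutral expectation a pooled sample of the"
    "\nfinal generation is judged against: a balanced pool should give a"
    "\nreconstructed heterozygous call."
)
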