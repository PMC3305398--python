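"""The cohort and population-genetic worked examples, computed from the
published counts.

Each block prints the statistic and what it means for the recessive
growth-stunting story: Mendelian segregation at birth, mortality
concentrated in mutant homozygotes, absence of adult homozygotes, and the
expected incidence among carrier-sire offspring.
"""

from stuntscan import cohortstats as cs

# 1) segregation at birth in the 105-calf prospective cohort
res = cs.segregation_test((26, 56, 23), (1, 2, 1), method="pearson")
print(f"birth genotypes 26:56:23 vs 1:2:1 -> chi2 = {res.statistic:.3f}, "
      f"p = {res.p_value:.2f}  (consistent with Mendelian segregation)")

# 2) death-or-culling by genotype: rows AA/AG/GG x (survived, event)
p = cs.genotype_outcome_exact_test([[26, 0], [55, 1], [6, 17]])
print(f"mortality association exact p = {p:.2e}  (< 0.0005)")

# 3) expected homozygote share among cases at risk-haplotype freq 0.52
hom = cs.hwe_genotype_freqs(0.52)[2]
print(f"expected homozygotes at q = 0.52: {hom:.4f} (~27%)")

# 4) no adult homozygote among 824 genotyped animals at q = 0.13
p0, expected = cs.prob_no_homozygotes(0.13, 824)
print(f"P(no GG among 824) = {p0:.2e}, expected GG count {expected:.1f}")

# 5) expected affected offspring of carrier bulls
print(f"expected affected offspring of carrier sires: "
      f"{cs.expected_affected_offspring(0.13, 'carrier'):.3f} (~6%)")

# 6) linkage disequilibrium between the variant and the risk haplotype
d, dp, r2 = cs.two_locus_ld(cs.TwoLocusHaplotypeCounts(49, 1, 0, 50))
print(f"LD of a near-perfectly coupled pair: D' = {dp:.2f}, r2 = {r2:.3f}")

# 7) carrier frequency in non-homozygous cases vs controls
f1, f2, p = cs.carrier_freq_comparison(29, 86, 211, 829)
print(f"carrier freq {f1:.0%} vs {f2:.0%}, exact p = {p:.2f}  "
      f"(no evidence of a second common mutation)")
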