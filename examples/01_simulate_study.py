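"""Generate one synthetic study: pedigree, SNP genotypes with an embedded
carrier haplotype, a prospective cohort and a qPCR table.

The printed counts describe the study realisation: how many individuals
descend from the founder carrier, how many carry the mutant allele, and
how mortality concentrates in mutant homozygotes.
"""

from stuntscan import simdata

cfg = simdata.SimConfig(
    seed=9, q0=0.3, n_founders=8, n_generations=6, mean_offspring=2.5,
    ai_sire_fraction=0.15, ai_mating_share=0.9,
)
ped = simdata.simulate_pedigree(cfg)
gm, truth = simdata.drop_haplotypes(ped, cfg)

print(f"pedigree: {len(ped.individuals)} individuals, "
      f"{len(ped.founders)} founders, mutation founder "
      f"{cfg.mutation_founder}")
print(f"genotypes: {gm.n_samples} samples x {gm.n_markers} markers, "
      f"mutation at {cfg.chrom}:{cfg.mutation_pos}")
print(f"true carriers: {(truth['dosage'] >= 1).sum()}, "
      f"affected homozygotes: {(truth['dosage'] == 2).sum()}")

# prospective cohort: 105 offspring of carrier x carrier matings
dosages = simdata.mendelian_carrier_cross_dosages(105, seed=3)
cohort = simdata.simulate_cohort(dosages, simdata.OutcomeModel(), seed=3)
print(f"cohort: {cohort.n_calves} calves, genotypes "
      f"{cohort.genotype_counts()}, dead-or-culled "
      f"{cohort.event_counts()}")
# About a third of GG calves die before 7 months; AA/AG almost never do.
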