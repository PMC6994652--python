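"""Simulate a complete heterografting experiment with planted truth.

Builds two homologous species genomes, a non-reference experimental genotype
per species, per-tissue expression, 5 planted mobile genes per direction and
all 8 RNA-seq libraries (4 roles x 2 replicates), then prints what was
planted.  Everything is reproducible from the single seed.
"""

from mobigraft import SimulationConfig, simulate_experiment

config = SimulationConfig(
    seed=1, n_contigs=1, contig_length=50_000, n_genes=30,
    genotype_snps=60, genotype_insertions=8, genotype_deletions=8,
    fragments_per_library=3_000, mobile_per_direction=5,
)
exp = simulate_experiment(config)

print(f"species1 genome: {exp.species1.reference.total_length:,} bp, "
      f"{len(exp.species1.genes)} genes")
print(f"species2 genome: {exp.species2.reference.total_length:,} bp "
      f"(derived at {config.interspecies_snp_rate:.0%} substitution divergence)")
for species, variants in exp.truth.genotype_variants.items():
    kinds = [v.kind for v in variants]
    print(f"{species} genotype layer: {kinds.count('SNP')} SNPs, "
          f"{kinds.count('INS')} insertions, {kinds.count('DEL')} deletions")
print(f"libraries: {len(exp.reads)} x {config.fragments_per_library:,} fragments")
for (direction, condition), table in sorted(exp.truth.mobile.items()):
    print(f"planted {direction} mobile genes ({condition}):")
    for gene, fraction in sorted(table.items()):
        print(f"  {gene}: transmission fraction {fraction:.3f}")
# The transmission fraction is the share of the donor gene's transcript pool
# that reaches the recipient tissue; detection must find these genes from
# reads alone.
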