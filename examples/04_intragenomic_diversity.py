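"""Intragenomic diversity of rrn operon copies, per region.

Generates genomes whose operon copies differ mostly in the ITS, then
computes pairwise distance matrices (SNVs per 100 comparable sites),
pooled identity summaries and cross-region Pearson correlations.
"""

from rrndb import cli, diversity, operon_extract, synth

config = synth.SynthConfig(
    n_genomes=8, n_lineages=2, copy_number=4, copy_number_dist="fixed",
    mutation_rates={"16S": 0.0005, "ITS": 0.01, "23S": 0.0005}, seed=3)
fixture = synth.generate_fixture(config)

operons = []
for genome_id, (contigs, features) in fixture.genomes.items():
    ops, _ = operon_extract.extract_genome_operons(contigs, features, genome_id)
    operons.extend(ops)

matrices = diversity.matrices_by_genome(operons)
table = diversity.long_format_table(matrices)

print(f"{'region':6s} {'mean id %':>10s} {'sd':>6s} {'frac diverse':>13s}")
for s in diversity.diversity_summary(matrices):
    print(f"{s.region:6s} {s.mean:10.3f} {s.sd:6.3f} "
          f"{s.fraction_genomes_diverse:13.2f}")

corr = diversity.region_correlation(table)
print("\nPearson r(rrn, ITS) =", round(corr.loc["rrn", "ITS"], 3))
print()
print("The ITS shows the lowest mean identity (it carries most of the "
      "planted mutations) and whole-operon diversity correlates "
      "strongly with ITS diversity, as expected when the spacer drives "
      "copy-to-copy variation. An SNV-count reading of an identity "
      "peak: diversity.snv_estimate(98.0, 4899) =",
      diversity.snv_estimate(98.0, 4899), "SNVs.")
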