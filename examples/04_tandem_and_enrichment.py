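"""Tandem clusters and gene-family association testing.

Finds tandem clusters in a simulated genome, then re-runs the published
tandem x disease-resistance-family association test from its printed
per-species counts (annotated genes, tandem genes, family genes, overlap).
"""

from synfrac.enrichment import table_from_counts, yates_chi2
from synfrac.io import filter_hits
from synfrac.model import HomologyHit
from synfrac.simulate import SimParams, run_simulation, synthetic_homology_rows
from synfrac.tandem import find_tandem, tandem_stats

res = run_simulation(SimParams(seed=3, genes_per_chromosome=80, codon_length=90,
                               tandem_birth_rate=5.0,
                               per_branch_loss_rate={"ref": 10.0, "A|B|C": 8.0,
                                                     "C": 8.0, "A|B": 8.0,
                                                     "A": 30.0, "B": 20.0}))
hits = [HomologyHit(r[0], r[1], r[2], r[11], r[10])
        for r in synthetic_homology_rows(res)]
genome = res.genomes["A"]
ids = set(genome.genes_by_id)
intra = filter_hits([h for h in hits if h.query_gene in ids and h.subject_gene in ids])
clusters = find_tandem(genome, intra, max_gap=5)
stats = tandem_stats(clusters, genome, reported_length=genome.genome_length / 1e6)
print(f"species A: {stats['tandem_genes']} tandem genes in {stats['n_clusters']} "
      f"clusters ({stats['percent_of_genes']}% of genes)")

print("\ntandem x NBS-LRR association from printed counts (genes, tandem, family, both):")
for name, counts in [("Jing rice", (40701, 5248, 492, 135)),
                     ("L. perrieri", (29114, 4149, 508, 162)),
                     ("O. meridionalis", (29442, 4079, 535, 66))]:
    r = yates_chi2(table_from_counts(*counts))
    print(f"  {name:<16} chi2={r.statistic:8.2f}  p={r.p:.3e}  ({r.direction})")
print("\nFamily members are over-represented among tandem genes wherever the")
print("corrected chi-squared p-value is small; the last species is the one")
print("published exception.")
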