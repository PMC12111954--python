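"""Full fractionation analysis of a simulated genome set.

Runs the complete reference-anchored analysis — blocks, Ks classification,
alignment table — then derives per-chromosome loss fractions, the
chromosome-ordinal trend, and Dollo branch loss rates, comparing the
recovered branch rates with the simulator's ground truth.
"""

from synfrac.loss import chromosome_loss, ordinal_trend
from synfrac.model import HomologyHit
from synfrac.pipeline import branch_loss_analysis, reference_analysis
from synfrac.simulate import SimParams, run_simulation, synthetic_homology_rows

res = run_simulation(SimParams(seed=1))
hits = [HomologyHit(r[0], r[1], r[2], r[11], r[10])
        for r in synthetic_homology_rows(res)]
ra = reference_analysis(res.genomes["ref"], res.genomes, hits, res.cds)

prof = chromosome_loss(ra.table, "A")
print(prof.per_chromosome[["chromosome", "n_ref", "n_retained", "loss_fraction"]]
      .to_string(index=False, float_format=lambda x: f"{x:.3f}"))
trend = ordinal_trend(prof, seed=1)
print(f"\nordinal trend: Spearman rho={trend['rho']:.3f}, permutation p={trend['p']:.4f}")
print("(loss fraction rises with chromosome ordinal, as simulated: the")
print(" generator ramps per-chromosome loss weights 0.7 -> 1.4)")

report = branch_loss_analysis(ra.table, res.tree, "ref")
ref_lin = {r.lineage for r in res.sim_genomes["ref"].records() if not r.tandem}
true_counts = res.truth.branch_loss_counts(restrict_lineages=ref_lin)
print("\nbranch        est_losses  true  rate(genes/My)")
for _, r in report.table.iterrows():
    print(f"{r['branch']:<12}  {r['losses']:>9}  {true_counts.get(r['branch'], 0):>4}"
          f"  {r['rate']:>8.1f}")
print("\nDollo parsimony places each gene's losses on the fewest branches")
print("explaining the leaf pattern; rates are counts over branch durations.")
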