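import numpy as np
import pytest

from synfrac.codons import IS_STOP
from synfrac.simulate import (SimParams, SimTruth, apply_wgd_and_fusions,
                              diverge_codon_pairs, emit_fixture, run_simulation,
                              simulate_ancestor, synthetic_homology_rows)


def small_params(**kw):
    base = dict(seed=5, genes_per_chromosome=30, codon_length=60)
    base.update(kw)
    return SimParams(**base)


class TestAncestor:
    def test_default_chromosome_count(self):
        anc = simulate_ancestor(SimParams(seed=0, genes_per_chromosome=5))
        assert anc.n_chromosomes == 7
        assert all(len(v) == 5 for v in anc.chromosomes.values())

    def test_empty_chromosomes_valid(self):
        anc = simulate_ancestor(SimParams(seed=0, genes_per_chromosome=0))
        assert anc.n_chromosomes == 7 and anc.n_genes == 0

    def test_no_internal_stops(self):
        anc = simulate_ancestor(SimParams(seed=1, genes_per_chromosome=10))
        for rec in anc.records():
            assert not IS_STOP[rec.cds].any()

    def test_same_seed_identical(self):
        a1 = simulate_ancestor(SimParams(seed=3, genes_per_chromosome=8))
        a2 = simulate_ancestor(SimParams(seed=3, genes_per_chromosome=8))
        for lbl in a1.chromosomes:
            for r1, r2 in zip(a1.chromosomes[lbl], a2.chromosomes[lbl]):
                assert r1.lineage == r2.lineage and (r1.cds == r2.cds).all()


class TestWgdAndFusions:
    def test_plain_wgd_doubles_chromosomes(self):
        anc = simulate_ancestor(small_params())
        root, truth = apply_wgd_and_fusions(anc, small_params(fusion_plan=()))
        assert root.n_chromosomes == 14
        assert root.n_genes == 2 * anc.n_genes
        for lin, partner in truth.paralog_partner.items():
            assert truth.paralog_partner[partner] == lin

    def test_default_plan_gives_twelve(self):
        anc = simulate_ancestor(small_params())
        root, _ = apply_wgd_and_fusions(anc, small_params())
        assert root.n_chromosomes == 12
        # relabelled by size: fused neo-chromosomes get the smallest ordinals
        sizes = [len(root.chromosomes[str(i)]) for i in range(1, 13)]
        assert sizes == sorted(sizes, reverse=True)

    def test_nested_fusion_rank_arithmetic(self):
        params = small_params(fusion_plan=(("8", "1", 0.5),))
        anc = simulate_ancestor(params)
        pre = [r.lineage for r in anc.chromosomes["1"]]
        root, _ = apply_wgd_and_fusions(anc, params)
        fused = next(recs for recs in root.chromosomes.values() if len(recs) == 60)
        lineages = [r.lineage for r in fused]
        k, nb = 15, 30  # insertion rank and donor size
        assert lineages[:k] == pre[:k]
        assert all(l.endswith("b") for l in lineages[k:k + nb])
        assert lineages[k + nb:] == pre[k:]  # former recipient genes shifted by |donor|

    def test_missing_chromosome_is_error(self):
        anc = simulate_ancestor(small_params())
        with pytest.raises(ValueError):
            apply_wgd_and_fusions(anc, small_params(fusion_plan=(("99", "1", 0.5),)))


class TestEvolution:
    def test_zero_rates_leaves_identical_to_root(self):
        params = small_params(per_branch_loss_rate=0.0, inversion_rate=0.0,
                              tandem_birth_rate=0.0, ds_per_my=0.0, wgd_pairwise_ds=0.0)
        res = run_simulation(params)
        assert not res.truth.loss_events and not res.truth.inversion_events
        assert not res.truth.tandem_events
        root_lineages = None
        for sp, g in res.sim_genomes.items():
            lin = [(lbl, r.lineage) for lbl, recs in g.chromosomes.items() for r in recs]
            if root_lineages is None:
                root_lineages = lin
            assert lin == root_lineages

    def test_loss_isolated_to_one_branch(self):
        params = small_params(per_branch_loss_rate={"A": 100.0}, inversion_rate=0.0,
                              tandem_birth_rate=0.0)
        res = run_simulation(params)
        branches = {b for _, b, _ in res.truth.loss_events}
        assert branches == {"A"}
        assert res.sim_genomes["B"].n_genes == res.sim_genomes["C"].n_genes == 2 * 7 * 30
        assert res.sim_genomes["A"].n_genes < 2 * 7 * 30

    def test_realized_loss_count_poisson_bounds(self):
        """Realized losses on an isolated branch stay within 3 sigma of the
        rate x duration expectation across seeds."""
        rate, duration = 40.0, 10.0   # branch C
        expected = rate * duration
        counts = []
        for seed in range(10):
            params = small_params(seed=seed, genes_per_chromosome=80,
                                  per_branch_loss_rate={"C": rate},
                                  inversion_rate=0.0, tandem_birth_rate=0.0)
            res = run_simulation(params)
            counts.append(sum(1 for _, b, _ in res.truth.loss_events if b == "C"))
        mean = float(np.mean(counts))
        assert abs(mean - expected) < 3 * np.sqrt(expected / len(counts))

    def test_conservation_invariant(self):
        """Per leaf: genes present + losses on the root-to-leaf path = root
        genes + tandem copies gained on that path."""
        res = run_simulation(small_params(genes_per_chromosome=50, tandem_birth_rate=3.0))
        root_n = 2 * 7 * 50
        paths = {"A": ["A|B|C", "A|B", "A"], "B": ["A|B|C", "A|B", "B"],
                 "C": ["A|B|C", "C"], "ref": ["ref"]}
        loss_by_branch = {}
        for _, b, _ in res.truth.loss_events:
            loss_by_branch[b] = loss_by_branch.get(b, 0) + 1
        gains = {}
        for b, _, n in res.truth.tandem_events:
            gains[b] = gains.get(b, 0) + n
        for sp, g in res.sim_genomes.items():
            n_loss = sum(loss_by_branch.get(b, 0) for b in paths[sp])
            n_gain = sum(gains.get(b, 0) for b in paths[sp])
            assert g.n_genes == root_n - n_loss + n_gain, sp

    def test_inversion_reverses_interval_and_strands(self):
        params = small_params(per_branch_loss_rate=0.0, tandem_birth_rate=0.0,
                              inversion_rate=0.0)
        res = run_simulation(params)
        base = res.sim_genomes["C"]
        params2 = small_params(per_branch_loss_rate=0.0, tandem_birth_rate=0.0,
                               inversion_rate=0.8)
        res2 = run_simulation(params2)
        assert res2.truth.inversion_events
        for branch, lbl, start, length in res2.truth.inversion_events:
            if branch != "C":
                continue
            inv = res2.sim_genomes["C"].chromosomes[lbl]
            ref = base.chromosomes[lbl]
            seg = [r.lineage for r in inv[start:start + length]]
            # the interval appears reversed relative to the no-inversion run
            # (unless hit by a second overlapping inversion)
            if seg == [r.lineage for r in ref[start:start + length]][::-1]:
                flipped = [a.strand != b.strand
                           for a, b in zip(inv[start:start + length],
                                           ref[start:start + length][::-1])]
                assert all(flipped)


class TestDeterminismAndFixture:
    def test_run_simulation_deterministic(self):
        r1 = run_simulation(small_params())
        r2 = run_simulation(small_params())
        assert r1.truth.loss_events == r2.truth.loss_events
        assert r1.truth.inversion_events == r2.truth.inversion_events
        for sp in r1.genomes:
            assert [g.id for g in r1.genomes[sp].genes()] == \
                   [g.id for g in r2.genomes[sp].genes()]
        for gid in list(r1.cds)[:50]:
            assert (r1.cds[gid] == r2.cds[gid]).all()

    def test_emit_fixture_manifest_and_rerun_identical(self, tmp_path):
        res = run_simulation(small_params(genes_per_chromosome=10))
        man = emit_fixture(res, tmp_path / "run1")
        for sp in ("ref", "A", "B", "C"):
            assert (tmp_path / "run1" / f"{sp}.gff3").exists()
            assert (tmp_path / "run1" / f"{sp}.cds.fasta").exists()
        assert (tmp_path / "run1" / "homology.tsv").exists()
        assert (tmp_path / "run1" / "truth" / "loss_events.tsv").exists()
        res2 = run_simulation(small_params(genes_per_chromosome=10))
        emit_fixture(res2, tmp_path / "run2")
        for name in ("A.gff3", "A.cds.fasta", "homology.tsv", "tree.nwk"):
            assert (tmp_path / "run1" / name).read_bytes() == \
                   (tmp_path / "run2" / name).read_bytes()

    def test_zero_noise_homology_is_exactly_family_pairs(self):
        res = run_simulation(small_params(genes_per_chromosome=10, noise_hits=0))
        fams = {}
        for sp, g in res.sim_genomes.items():
            for r in g.records():
                fams.setdefault(r.family, set()).add(g.gene_id(r))
        expected = sum(len(m) * (len(m) - 1) for m in fams.values())  # both directions
        assert len(synthetic_homology_rows(res)) == expected


class TestDsRecovery:
    @pytest.mark.parametrize("target", [0.1, 0.3, 0.6])
    def test_ng86_recovers_target_ds(self, target):
        from synfrac.ks import ng86_pairs
        a, b = diverge_codon_pairs(120, 500, target, seed=17)
        est = ng86_pairs(a, b)["dS"]
        assert abs(float(np.nanmean(est)) - target) < 0.05
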