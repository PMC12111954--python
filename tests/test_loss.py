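import itertools
import math

import dendropy
import numpy as np
import pandas as pd
import pytest

from synfrac.alignment_table import build_table
from synfrac.loss import (RetentionProfile, branch_rates, brute_force_dollo,
                          chromosome_loss, dollo_assign, loss_rate,
                          ordinal_trend, percent_excess, split_subgenomes,
                          tree_branch_durations)
from synfrac.model import SpeciesTree

from conftest import make_genome
from test_alignment_table import make_block, ref_genome


class TestChromosomeLoss:
    def test_fraction(self):
        ref = make_genome("ref", [(f"r{i}", "1", 100 * i + 1) for i in range(10)])
        blk = make_block(ref, "X", [(f"r{i}", f"x{i}", i) for i in range(6)])
        table = build_table(ref, {"X": [blk]})
        prof = chromosome_loss(table, "X")
        row = prof.per_chromosome.iloc[0]
        assert row["n_ref"] == 10 and row["n_retained"] == 6
        assert row["loss_fraction"] == pytest.approx(0.40)

    def test_all_filled_zero_loss(self):
        ref = ref_genome()
        blk = make_block(ref, "X", [(f"r{i}", f"x{i}", i) for i in range(6)])
        table = build_table(ref, {"X": [blk]})
        prof = chromosome_loss(table, "X")
        assert (prof.per_chromosome["loss_fraction"] == 0).all()

    def test_windows_half_open(self):
        # genes at 0.5 Mb and exactly 1.0 Mb fall in different windows
        ref = make_genome("ref", [("r0", "1", 500_000), ("r1", "1", 1_000_000)])
        blk = make_block(ref, "X", [("r0", "x0", 0)])
        table = build_table(ref, {"X": [blk]})
        prof = chromosome_loss(table, "X")
        w = prof.per_window
        assert len(w) == 2
        assert w.iloc[0]["retained_fraction"] == 1.0   # r0 retained
        assert w.iloc[1]["retained_fraction"] == 0.0   # r1 absent

    def test_conservation_total_absent(self, sim_analysis):
        from synfrac.alignment_table import ABSENT
        table = sim_analysis.table
        prof = chromosome_loss(table, "A")
        total_lost = int((prof.per_chromosome["n_ref"] - prof.per_chromosome["n_retained"]).sum())
        absent_cells = sum(table.get(g, "A") == ABSENT for g in table.ref_genes)
        assert total_lost == absent_cells


def _profile_from_fractions(fracs):
    df = pd.DataFrame({
        "chromosome": [str(i + 1) for i in range(len(fracs))],
        "chrom_ordinal": list(range(1, len(fracs) + 1)),
        "n_ref": 100, "n_retained": [int(100 * (1 - f)) for f in fracs],
        "loss_fraction": fracs,
    })
    return RetentionProfile(species="X", per_chromosome=df, per_window=pd.DataFrame())


class TestOrdinalTrend:
    def test_strictly_increasing(self):
        r = ordinal_trend(_profile_from_fractions([0.1, 0.2, 0.3, 0.4, 0.5]))
        assert r["rho"] == pytest.approx(1.0)

    def test_strictly_decreasing(self):
        r = ordinal_trend(_profile_from_fractions([0.5, 0.4, 0.3, 0.2, 0.1]))
        assert r["rho"] == pytest.approx(-1.0)

    def test_flat_fractions(self):
        r = ordinal_trend(_profile_from_fractions([0.3] * 5))
        assert r["rho"] == 0.0 and r["p"] == 1.0

    def test_permutation_matches_exact_enumeration(self):
        fracs = [0.12, 0.35, 0.28, 0.44, 0.40]
        exact = ordinal_trend(_profile_from_fractions(fracs), method="exact")
        perm = ordinal_trend(_profile_from_fractions(fracs),
                             n_permutations=20_000, seed=3)
        # MC error at 20k draws: 3 sigma ~ 3*sqrt(p(1-p)/n)
        tol = 3 * math.sqrt(exact["p"] * (1 - exact["p"]) / 20_000) + 1e-9
        assert abs(perm["p"] - exact["p"]) <= tol


class TestSplitSubgenomes:
    def _region(self, genes_a, genes_b, ord_a=3, ord_b=7):
        return {"region_id": "reg0", "genes_a": genes_a, "genes_b": genes_b,
                "chrom_a": str(ord_a), "chrom_b": str(ord_b),
                "ordinal_a": ord_a, "ordinal_b": ord_b}

    def _table(self, retained):
        ref = make_genome("ref", [(f"r{i}", "1", 100 * i + 1) for i in range(22)])
        pairs = [(g, g.replace("r", "x"), i) for i, g in enumerate(retained)]
        blk = make_block(ref, "X", pairs)
        return build_table(ref, {"X": [blk]})

    def test_more_retained_copy_wins(self):
        genes_a = [f"r{i}" for i in range(8)]          # 8 retained
        genes_b = [f"r{i}" for i in range(8, 16)]      # 3 retained
        table = self._table(genes_a + genes_b[:3])
        part = split_subgenomes(table, [self._region(genes_a, genes_b)], "X")
        row = part.assignments.iloc[0]
        assert row["side_more"] == "a" and row["retained_more"] == 8

    def test_tie_breaks_to_lower_ordinal(self):
        genes_a = [f"r{i}" for i in range(5)]
        genes_b = [f"r{i}" for i in range(5, 10)]
        table = self._table(genes_a + genes_b)         # 5 vs 5
        part = split_subgenomes(table, [self._region(genes_a, genes_b, ord_a=7, ord_b=3)], "X")
        assert part.assignments.iloc[0]["side_more"] == "b"  # chromosome 3 copy

    def test_fully_lost_region_excluded(self):
        genes_a = [f"r{i}" for i in range(3)]
        genes_b = [f"r{i}" for i in range(3, 6)]
        table = self._table([])
        part = split_subgenomes(table, [self._region(genes_a, genes_b)], "X")
        assert part.n_excluded == 1 and part.assignments.empty


def _tree(newick):
    return SpeciesTree.from_newick(newick)


class TestDollo:
    def test_absent_everywhere_charges_ingroup_stem(self):
        tree = _tree("(ref:35,((A:1,B:1):9,C:10):25);")
        counts = dollo_assign({"g": {"A": False, "B": False, "C": False}},
                              tree, reference_species="ref")
        d = dict(zip(counts["branch"], counts["losses"]))
        assert d["A|B|C"] == 1 and sum(d.values()) == 1

    def test_single_leaf_absence_charges_terminal(self):
        tree = _tree("(ref:35,((A:1,B:1):9,C:10):25);")
        counts = dollo_assign({"g": {"A": False, "B": True, "C": True}},
                              tree, reference_species="ref")
        d = dict(zip(counts["branch"], counts["losses"]))
        assert d["A"] == 1 and sum(d.values()) == 1

    def test_sister_absence_charges_common_branch(self):
        tree = _tree("(ref:35,((A:1,B:1):9,C:10):25);")
        counts = dollo_assign({"g": {"A": False, "B": False, "C": True}},
                              tree, reference_species="ref")
        d = dict(zip(counts["branch"], counts["losses"]))
        assert d["A|B"] == 1 and sum(d.values()) == 1

    @pytest.mark.parametrize("newick", [
        "(((((((A:1,B:1):1,C:1):1,D:1):1,E:1):1,F:1):1,G:1):1,H:1);",  # caterpillar
        "(((A:1,B:1):1,(C:1,D:1):1):1,((E:1,F:1):1,(G:1,H:1):1):1);",  # balanced
    ])
    def test_exhaustive_minimality_on_eight_leaf_trees(self, newick):
        """Dollo assignment equals the brute-force minimal branch cover for
        every presence pattern over 8 leaves."""
        tree = _tree(newick)
        leaves = tree.leaf_labels
        for bits in range(256):
            pattern = {lf: bool(bits >> i & 1) for i, lf in enumerate(leaves)}
            counts = dollo_assign({"g": pattern}, tree)
            assigned = int(counts["losses"].sum())
            minimal = brute_force_dollo(tree.tree, pattern)
            assert assigned == minimal, (bits, pattern)


class TestBranchRates:
    def test_published_rate_arithmetic(self):
        assert loss_rate(7354, 5.0) == pytest.approx(1470.8)
        assert round(loss_rate(417, 0.36)) == 1158
        assert percent_excess(2193 / 1.0, 1229 / 1.0) == 78.4

    def test_rates_from_counts_and_tree(self):
        tree = _tree("(ref:35,((A:1,B:1):9,C:10):25);")
        durations = tree_branch_durations(tree, reference_species="ref")
        counts = pd.DataFrame([{"branch": "A|B|C", "losses": 875},
                               {"branch": "A", "losses": 150}])
        rep = branch_rates(counts, durations)
        d = dict(zip(rep.table["branch"], rep.table["rate"]))
        assert d["A|B|C"] == pytest.approx(35.0)
        assert d["A"] == pytest.approx(150.0)

    def test_zero_duration_gives_nan(self):
        rep = branch_rates(pd.DataFrame([{"branch": "x", "losses": 5}]), {"x": 0.0})
        assert math.isnan(rep.table["rate"].iloc[0])
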