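import math

import numpy as np
import pytest

from synfrac.codons import FOURFOLD_CODES, IS_STOP, decode_cds
from synfrac.ks import (block_ks, classify_block, ks_to_time, make_codon_alignment,
                        ng86, ng86_pairs, rate_correct)
from synfrac.simulate import diverge_codon_pairs


def _random_codon_string(rng, n, fourfold=False):
    if fourfold:
        return decode_cds(rng.choice(FOURFOLD_CODES, n))
    codes = rng.choice(np.flatnonzero(~IS_STOP), n)
    return decode_cds(codes)


class TestNg86:
    def test_identical_sequences(self):
        kv = ng86(make_codon_alignment("ATGGCT" * 10, "ATGGCT" * 10))
        assert kv.Sd == kv.Nd == 0 and kv.dS == 0 and kv.dN == 0

    def test_hand_computed_fourfold_example(self):
        # GGT's third position is fully synonymous, positions 1-2 fully
        # nonsynonymous: S=1, N=2 per codon.
        a = "GGT" * 100
        b = "GGC" * 10 + "GGT" * 90
        kv = ng86(make_codon_alignment(a, b))
        assert kv.S == pytest.approx(100) and kv.N == pytest.approx(200)
        assert kv.Sd == 10 and kv.Nd == 0
        assert kv.pS == pytest.approx(0.1)
        assert kv.dS == pytest.approx(-0.75 * math.log(1 - 0.4 / 3), abs=1e-9)
        assert kv.dS == pytest.approx(0.10733, abs=1e-5)
        assert kv.dN == 0

    def test_saturation_flag(self):
        # engineer pS >= 3/4: 85 of 100 third positions differ
        a = "GGT" * 100
        b = "GGC" * 85 + "GGT" * 15
        kv = ng86(make_codon_alignment(a, b))
        assert not kv.defined and math.isnan(kv.dS)

    def test_symmetry_exact(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            a = _random_codon_string(rng, 40)
            b = _random_codon_string(rng, 40)
            ka = ng86(make_codon_alignment(a, b))
            kb = ng86(make_codon_alignment(b, a))
            assert (ka.S, ka.N, ka.Sd, ka.Nd) == (kb.S, kb.N, kb.Sd, kb.Nd)

    def test_site_conservation(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            a = _random_codon_string(rng, 33)
            b = _random_codon_string(rng, 33)
            kv = ng86(make_codon_alignment(a, b))
            assert kv.S + kv.N == pytest.approx(3 * 33, abs=1e-9)

    def test_against_independent_ng86_implementation(self):
        """Cross-check dN/dS against biopython's NG86 on random codon pairs.

        The implementations differ only in the stop-pathway convention
        (biopython scores stop->stop steps as synonymous instead of
        excluding stop-routed pathways), so codon columns whose mutational
        pathways touch a stop are dropped before comparing.
        """
        import itertools as it

        from Bio.Align import Alignment, analysis
        from Bio.Seq import Seq

        from synfrac.codons import IS_STOP, codon_code, codon_str

        def stop_routed(ca, cb):
            pa = [(ca >> 4) & 3, (ca >> 2) & 3, ca & 3]
            pb = [(cb >> 4) & 3, (cb >> 2) & 3, cb & 3]
            diff = [i for i in range(3) if pa[i] != pb[i]]
            for order in it.permutations(diff):
                cur = list(pa)
                for pos in order:
                    cur[pos] = pb[pos]
                    code = (cur[0] << 4) | (cur[1] << 2) | cur[2]
                    if IS_STOP[code]:
                        return True
            return False

        rng = np.random.default_rng(3)
        for _ in range(10):
            a = _random_codon_string(rng, 60)
            b = a[:120] + _random_codon_string(rng, 60, fourfold=True)[120:]
            cods = [(a[i:i + 3], b[i:i + 3]) for i in range(0, 180, 3)]
            kept = [(x, y) for x, y in cods
                    if not stop_routed(codon_code(x), codon_code(y))]
            aa = "".join(x for x, _ in kept)
            bb = "".join(y for _, y in kept)
            mine = ng86(make_codon_alignment(aa, bb))
            aln = Alignment([Seq(aa), Seq(bb)], np.array([[0, len(aa)], [0, len(bb)]]))
            dn, ds = analysis.calculate_dn_ds(aln, method="NG86")
            if mine.defined:
                assert mine.dS == pytest.approx(ds, abs=1e-9)
            if mine.dn_defined:
                assert mine.dN == pytest.approx(dn, abs=1e-9)

    def test_vectorised_matches_scalar(self):
        a, b = diverge_codon_pairs(5, 50, 0.3, seed=1)
        res = ng86_pairs(a, b)
        for i in range(5):
            kv = ng86(make_codon_alignment(decode_cds(a[i]), decode_cds(b[i])))
            assert res["dS"][i] == pytest.approx(kv.dS, abs=1e-12)
            assert res["S"][i] == pytest.approx(kv.S, abs=1e-9)

    def test_empty_alignment_is_error(self):
        from synfrac.ks import CodonAlignment
        with pytest.raises(ValueError):
            ng86(CodonAlignment(np.array([], dtype=int), np.array([], dtype=int)))


class TestCodonAlignment:
    def test_equal_length_keeps_all_codons(self):
        aln = make_codon_alignment("ATGGCT", "ATGGCA")
        assert aln.n_codons == 2 and aln.n_dropped == 0

    def test_gapped_protein_column_dropped(self):
        # protein alignment MA- vs MAV threads codons, dropping the gap column
        aln = make_codon_alignment("ATGGCT", "ATGGCTGTT", protein_alignment=("MA-", "MAV"))
        assert aln.n_codons == 2 and aln.n_dropped == 1

    def test_stop_column_dropped(self):
        aln = make_codon_alignment("ATGTAA", "ATGGCA")
        assert aln.n_codons == 1 and aln.n_dropped == 1

    def test_unequal_without_protein_alignment_is_error(self):
        with pytest.raises(ValueError):
            make_codon_alignment("ATGGCT", "ATGGCTGTT")

    def test_simulator_pair_length(self):
        a, b = diverge_codon_pairs(1, 500, 0.2, seed=0)
        aln = make_codon_alignment(decode_cds(a[0]), decode_cds(b[0]))
        assert aln.n_codons == 500


class TestBlockKs:
    def test_median(self):
        assert block_ks([0.55, 0.60, 0.65]) == (pytest.approx(0.60), 0)

    def test_nan_excluded(self):
        ks, n_undef = block_ks([0.6, float("nan")])
        assert ks == pytest.approx(0.6) and n_undef == 1

    def test_all_undefined(self):
        ks, n_undef = block_ks([float("nan")] * 3)
        assert math.isnan(ks) and n_undef == 3

    def test_simulated_gct_blocks_near_target(self, sim_analysis, sim_default):
        target = sim_default.params.wgd_pairwise_ds
        vals = [b.ks for b in sim_analysis.ref_self_blocks if b.homology_class == "gct_paralog"]
        assert len(vals) >= 5
        assert abs(float(np.median(vals)) - target) < 0.05


class TestClassify:
    @pytest.mark.parametrize("ks,expected", [
        (0.2, "ortholog"), (0.6, "gct_paralog"), (0.35, "unclassified"),
        (0.95, "unclassified"), (float("nan"), "unclassified"),
    ])
    def test_windows(self, ks, expected):
        assert classify_block(ks) == expected

    def test_bad_thresholds(self):
        with pytest.raises(ValueError):
            classify_block(0.5, t_orth=0.5, t_lo=0.4, t_hi=0.9)


class TestKsToTime:
    def test_closed_form(self):
        assert ks_to_time(0.0, 6.5e-9) == 0.0
        assert ks_to_time(0.6, 6.5e-9) == pytest.approx(46.15, abs=0.01)

    def test_doubling_rate_halves_time(self):
        for ks in (0.1, 0.37, 0.8):
            assert ks_to_time(ks, 2 * 6.5e-9) == pytest.approx(ks_to_time(ks, 6.5e-9) / 2)

    def test_nan_propagates(self):
        assert math.isnan(ks_to_time(float("nan"), 6.5e-9))


class TestRateCorrect:
    def test_matching_mode_scale_near_one(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(0.6, 0.05, 400).clip(0.01)
        _, factors = rate_correct({"ref": vals, "x": vals.copy()}, "ref")
        assert factors["x"] == pytest.approx(1.0, abs=0.02)

    def test_faster_clock_recovered(self):
        rng = np.random.default_rng(1)
        base = rng.normal(0.6, 0.05, 500).clip(0.01)
        _, factors = rate_correct({"ref": base, "fast": base * 1.5}, "ref")
        assert factors["fast"] == pytest.approx(1 / 1.5, rel=0.10)

    def test_empty_set_is_error(self):
        with pytest.raises(ValueError):
            rate_correct({"ref": np.array([])}, "ref")
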