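"""Spreading classification rule, isoform counting, uCpG landscapes."""

import warnings

import numpy as np
import pytest

from fpspread.spreading import (
    assign_gene_targets,
    classify_all,
    classify_spreading,
    keep_isoform_pairs,
    split_by_cofactor,
    spreading_summary,
    ucpg_landscape,
)

from conftest import gene, gi, peak, track


def one_call(p, g, threshold=4000):
    calls = classify_all([p], [g], spread_threshold=threshold)
    assert len(calls) == 1
    return calls[0]


class TestTargetAssignment:
    def test_tss_inside_peak_half_open(self):
        g = gene(10000, 30000, "+")
        assert len(assign_gene_targets([peak(9000, 10001)], [g])) == 1
        # peak ending exactly at the TSS does not cover it
        assert len(assign_gene_targets([peak(9000, 10000)], [g])) == 0
        # peak starting at the TSS covers it
        assert len(assign_gene_targets([peak(10000, 11000)], [g])) == 1

    def test_minus_strand_tss(self):
        g = gene(10000, 30000, "-")  # tss = 29999
        assert len(assign_gene_targets([peak(29999, 30050)], [g])) == 1
        assert len(assign_gene_targets([peak(29000, 29999)], [g])) == 0

    def test_all_pairs_emitted(self):
        g1 = gene(10000, 30000, "+", gene_id="a", isoform_id="a.1")
        g2 = gene(10000, 30000, "+", gene_id="a", isoform_id="a.2")
        p1, p2 = peak(9000, 11000), peak(9500, 10500)
        calls = assign_gene_targets([p1, p2], [g1, g2])
        assert len(calls) == 4


class TestSpreadingRule:
    def test_plus_strand_length(self):
        g = gene(10000, 30000, "+")
        c = one_call(peak(9000, 14500), g)
        assert c.spreading_length == 4500
        assert c.is_spreading and not c.exceeds_tes

    def test_threshold_is_strict(self):
        g = gene(10000, 30000, "+")
        assert not one_call(peak(9000, 14000), g).is_spreading  # exactly 4000
        assert one_call(peak(9000, 14001), g).is_spreading  # 4001

    def test_edge_at_tes_is_spreading(self):
        g = gene(10000, 30000, "+")  # tes = 29999
        c = one_call(peak(9000, 30000), g)  # last covered base = 29999 = tes
        assert c.is_spreading and not c.exceeds_tes

    def test_one_bp_past_tes_is_not(self):
        g = gene(10000, 30000, "+")
        c = one_call(peak(9000, 30001), g)
        assert c.exceeds_tes and not c.is_spreading

    def test_minus_strand_worked_example(self):
        # minus-strand gene over [10000, 30000): tss = 29999, tes = 10000
        g = gene(10000, 30000, "-")
        c = one_call(peak(24000, 30050), g)
        assert c.spreading_length == 29999 - 24000 == 5999
        assert c.is_spreading and not c.exceeds_tes

    def test_minus_strand_boundaries(self):
        g = gene(10000, 30000, "-")
        assert not one_call(peak(25999, 30050), g).is_spreading  # length 4000
        assert one_call(peak(25998, 30050), g).is_spreading  # length 4001
        # peak start exactly at TES: allowed
        assert one_call(peak(10000, 30050), g).is_spreading
        # one bp past the TES: exceeds
        c = one_call(peak(9999, 30050), g)
        assert c.exceeds_tes and not c.is_spreading

    def test_upstream_extension_is_free(self):
        g = gene(100000, 130000, "+")
        c = one_call(peak(20000, 105000), g)  # 80 kb upstream
        assert c.is_spreading

    def test_strand_mirror(self, rng):
        """Configurations built to have equal spreading lengths on both
        strands receive identical verdicts."""
        for _ in range(500):
            length = int(rng.integers(1, 9000))
            gene_len = int(rng.integers(max(length, 2) + 1, 20000) + 2)
            gp = gene(50000, 50000 + gene_len, "+")
            gm = gene(50000, 50000 + gene_len, "-")
            up = int(rng.integers(1, 2000))
            pp = peak(gp.tss - up, gp.tss + length)
            pm = peak(gm.tss - length, gm.tss + up)
            cp = one_call(pp, gp)
            cm = one_call(pm, gm)
            assert cp.spreading_length == cm.spreading_length == length
            assert cp.is_spreading == cm.is_spreading
            assert cp.exceeds_tes == cm.exceeds_tes

    def test_threshold_monotonicity(self, rng):
        g = gene(10000, 40000, "+")
        p = peak(9000, 22000)
        verdicts = [
            one_call(p, g, threshold=t).is_spreading for t in (0, 2000, 11999, 12000, 30000)
        ]
        # once false, never true again as the threshold grows
        assert verdicts == sorted(verdicts, reverse=True)

    def test_bruteforce_oracle(self, rng):
        """Independent literal re-derivation of the rule on random configs."""
        for _ in range(3000):
            strand = "+" if rng.random() < 0.5 else "-"
            gs = int(rng.integers(1000, 50000))
            ge = gs + int(rng.integers(2, 40000))
            ps = int(rng.integers(0, 80000))
            pe = ps + int(rng.integers(1, 40000))
            g = gene(gs, ge, strand)
            p = peak(ps, pe)
            calls = classify_all([p], [g])
            # oracle: literal reading
            tss = gs if strand == "+" else ge - 1
            tes = ge - 1 if strand == "+" else gs
            target = ps <= tss < pe
            if strand == "+":
                length, exceeds = pe - tss, pe - 1 > tes
            else:
                length, exceeds = tss - ps, ps < tes
            spreading = target and length > 4000 and not exceeds
            assert len(calls) == (1 if target else 0)
            if target:
                assert calls[0].spreading_length == length
                assert calls[0].exceeds_tes == exceeds
                assert calls[0].is_spreading == spreading


class TestIsoformCounting:
    def test_identical_isoforms_collapse(self):
        p = peak(9000, 16000)
        g1 = gene(10000, 30000, "+", gene_id="a", isoform_id="a.1")
        g2 = gene(10000, 30000, "+", gene_id="a", isoform_id="a.2")
        calls = classify_all([p], [g1, g2])
        assert len(calls) == 2
        assert len(keep_isoform_pairs(calls)) == 1

    def test_distinct_tss_isoforms_kept(self):
        p = peak(9000, 16000)
        g1 = gene(10000, 30000, "+", gene_id="a", isoform_id="a.1")
        g2 = gene(10500, 30000, "+", gene_id="a", isoform_id="a.2")
        calls = classify_all([p], [g1, g2])
        kept = keep_isoform_pairs(calls)
        assert len(kept) == 2
        summary = spreading_summary(calls)
        assert summary["n_spreading_pairs"] == 2
        assert summary["n_spreading_genes"] == 1

    def test_summary_counts(self):
        p1 = peak(9000, 16000)
        p2 = peak(49000, 50500)
        ga = gene(10000, 30000, "+", gene_id="a")
        gb = gene(50000, 70000, "+", gene_id="b")
        s = spreading_summary(classify_all([p1, p2], [ga, gb]))
        assert s == {
            "n_target_pairs": 2,
            "n_target_genes": 2,
            "n_spreading_pairs": 1,
            "n_spreading_genes": 1,
            "fraction_spreading_pairs": 0.5,
        }


class TestUcpgLandscape:
    def _call(self):
        g = gene(10000, 30000, "+")
        return one_call(peak(9500, 16000), g)

    def test_gaps_and_max_gap(self):
        c = self._call()
        islands = [gi(9600, 9900), gi(10400, 10700), gi(12000, 12300)]
        ls = ucpg_landscape(c, islands)
        assert [u.start for u in ls.ucpg_under] == [9600, 10400, 12000]
        assert ls.gaps == [500, 1300]
        assert ls.max_gap == 1300

    def test_overlapping_islands_gap_zero(self):
        c = self._call()
        ls = ucpg_landscape(c, [gi(9600, 10500), gi(10400, 10700)])
        assert ls.gaps == [0]

    def test_bookend_tolerance_boundary(self):
        c = self._call()  # peak edges 9500 and 15999
        # island starting exactly tol past the left edge: bookended
        ls = ucpg_landscape(c, [gi(10500, 10800), gi(15900, 16200)])
        assert ls.bookended_start and ls.bookended_end
        # 1 bp further: not bookended
        ls2 = ucpg_landscape(c, [gi(10501, 10800), gi(15900, 16200)])
        assert not ls2.bookended_start

    def test_island_covering_edge_is_distance_zero(self):
        c = self._call()
        ls = ucpg_landscape(c, [gi(9400, 9700)])
        assert ls.bookended_start

    def test_no_islands_warns(self):
        c = self._call()
        with pytest.warns(UserWarning, match="no uCpG"):
            ls = ucpg_landscape(c, [gi(50000, 50300)])
        assert ls.ucpg_under == [] and not ls.bookended_start

    def test_only_overlapping_islands_counted(self):
        c = self._call()
        ls = ucpg_landscape(c, [gi(9000, 9501), gi(16000, 16300)])
        # first island overlaps 1 bp; second starts exactly at peak.end
        assert len(ls.ucpg_under) == 1


class TestCofactorSplit:
    def test_split_by_planted_signal(self):
        values = np.zeros(1000)
        values[100:200] = 50.0  # hot
        values[400:500] = 1.0  # cold
        t = track(values, bin_size=1)
        hot, cold = peak(100, 200, name="hot"), peak(400, 500, name="cold")
        high, low, sig = split_by_cofactor([hot, cold], t)
        assert [p.name for p in high] == ["hot"]
        assert [p.name for p in low] == ["cold"]
        assert len(sig) == 2

    def test_all_equal_warns_empty_high(self):
        t = track(np.ones(1000), bin_size=1)
        peaks = [peak(0, 100), peak(200, 300)]
        with pytest.warns(UserWarning, match="empty high"):
            high, low, _ = split_by_cofactor(peaks, t)
        assert high == [] and len(low) == 2
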