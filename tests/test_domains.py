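"""Enhancer stitching, super-enhancer cutoff, broad domains, partitions."""

import numpy as np
import pytest

from fpspread.domains import (
    assign_region_targets,
    broad_domains,
    call_super_enhancers,
    rank_signal_cutoff,
    stitch_enhancers,
    three_way_partition,
)

from conftest import gene, gi, peak, track


def _stitch_oracle(peaks, stitch_distance):
    """Union-find over pairs with gap <= stitch_distance (no TSS exclusion)."""
    n = len(peaks)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = peaks[i], peaks[j]
            if a.chrom != b.chrom:
                continue
            gap = max(a.start, b.start) - min(a.end, b.end)
            if gap <= stitch_distance:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(peaks[i])
    return sorted(
        (min(p.start for p in g), max(p.end for p in g)) for g in groups.values()
    )


class TestStitching:
    def test_gap_at_distance_merges(self):
        out = stitch_enhancers([peak(0, 1000), peak(13500, 14000)], stitch_distance=12500)
        assert len(out) == 1
        assert (out[0].interval.start, out[0].interval.end) == (0, 14000)

    def test_gap_one_past_distance_does_not(self):
        out = stitch_enhancers([peak(0, 1000), peak(13501, 14000)], stitch_distance=12500)
        assert len(out) == 2

    def test_overlapping_always_merge(self):
        out = stitch_enhancers([peak(0, 1000), peak(500, 2000)], stitch_distance=0)
        assert len(out) == 1

    def test_tss_in_gap_blocks_merge(self):
        g = gene(5000, 20000, "+")  # tss = 5000
        peaks = [peak(0, 1000), peak(8000, 9000)]
        merged = stitch_enhancers(peaks, stitch_distance=12500, genes=None)
        blocked = stitch_enhancers(peaks, stitch_distance=12500, genes=[g])
        assert len(merged) == 1 and len(blocked) == 2

    def test_tss_window_boundary(self):
        # gap [1000, 8000); tss window = [tss-2500, tss+2501)
        g_inside = gene(3000, 30000, "+")  # window [500, 5501) overlaps gap
        g_outside = gene(10500, 30000, "+")  # window [8000, 13001): touches gap end only
        peaks = [peak(0, 1000), peak(8000, 9000)]
        assert len(stitch_enhancers(peaks, genes=[g_inside])) == 2
        assert len(stitch_enhancers(peaks, genes=[g_outside])) == 1

    def test_matches_union_find_oracle(self, rng):
        for _ in range(30):
            peaks = []
            for _ in range(int(rng.integers(5, 40))):
                s = int(rng.integers(0, 500000))
                peaks.append(peak(s, s + 1 + int(rng.integers(100, 3000))))
            d = int(rng.choice([0, 2000, 12500, 40000]))
            out = stitch_enhancers(peaks, stitch_distance=d)
            got = sorted((e.interval.start, e.interval.end) for e in out)
            assert got == _stitch_oracle(peaks, d)

    def test_idempotent(self, rng):
        peaks = []
        for _ in range(50):
            s = int(rng.integers(0, 500000))
            peaks.append(peak(s, s + 1 + int(rng.integers(100, 3000))))
        once = stitch_enhancers(peaks)
        again = stitch_enhancers([peak(e.interval.start, e.interval.end) for e in once])
        assert [(e.interval.start, e.interval.end) for e in again] == [
            (e.interval.start, e.interval.end) for e in once
        ]

    def test_monotone_in_distance(self, rng):
        peaks = []
        for _ in range(60):
            s = int(rng.integers(0, 300000))
            peaks.append(peak(s, s + 1 + int(rng.integers(100, 2000))))
        counts = [len(stitch_enhancers(peaks, stitch_distance=d)) for d in (0, 1000, 5000, 20000)]
        assert counts == sorted(counts, reverse=True)


class TestRankSignalCutoff:
    def test_linear_curve_cuts_at_midpoint(self):
        s = np.arange(1.0, 101.0)
        cutoff = rank_signal_cutoff(s)
        # upper half super: cutoff at the median of the tied diagonal
        assert np.isclose(cutoff, 50.0, atol=1.0)
        assert (s > cutoff).sum() == pytest.approx(50, abs=1)

    def test_two_regime_curve_cuts_at_break(self):
        s = np.concatenate([np.linspace(1, 3, 90), np.linspace(50, 100, 10)])
        cutoff = rank_signal_cutoff(s)
        assert 3 <= cutoff < 50
        assert (s > cutoff).sum() == 10

    def test_all_equal_returns_none(self):
        assert rank_signal_cutoff(np.full(50, 7.0)) is None

    def test_affine_invariance_of_selection(self, rng):
        s = rng.lognormal(0, 1, 200)
        base = rank_signal_cutoff(s)
        scaled = rank_signal_cutoff(3.5 * s + 11.0)
        assert (s > base).sum() == (3.5 * s + 11.0 > scaled).sum()

    def test_too_few_points(self):
        assert rank_signal_cutoff(np.array([1.0, 2.0])) is None


class TestSuperEnhancerCalling:
    def test_planted_top_decile_called(self, rng):
        n = 10000
        values = np.zeros(400000)
        amps = np.concatenate([rng.uniform(1, 3, 54), rng.uniform(15, 25, 6)])
        peaks = []
        for i, a in enumerate(amps):
            s = i * 6000
            values[s : s + 2000] = a
            peaks.append(peak(s, s + 2000, name=f"e{i}"))
        t = track(values, bin_size=1, total_reads=1e7)
        stitched = stitch_enhancers(peaks, stitch_distance=0)
        called = call_super_enhancers(stitched, t)
        supers = {e.constituents[0].name for e in called if e.is_super}
        assert supers == {f"e{i}" for i in range(54, 60)}
        ranks = sorted(e.rank for e in called if e.is_super)
        assert ranks == [1, 2, 3, 4, 5, 6]

    def test_control_subtraction(self):
        values = np.zeros(30000)
        values[0:1000] = 10
        values[10000:11000] = 10
        values[20000:21000] = 2
        signal = track(values.copy(), bin_size=1, total_reads=1e7)
        ctrl_values = np.zeros(30000)
        ctrl_values[0:1000] = 9.5  # knocks the first one down
        control = track(ctrl_values, bin_size=1, total_reads=1e7)
        stitched = stitch_enhancers(
            [peak(0, 1000, name="a"), peak(10000, 11000, name="b"), peak(20000, 21000, name="c")],
            stitch_distance=0,
        )
        called = call_super_enhancers(stitched, signal, control)
        by_name = {e.constituents[0].name: e for e in called}
        assert by_name["b"].signal > by_name["a"].signal

    def test_fewer_than_three_warns_none_super(self):
        t = track(np.ones(10000), bin_size=1, total_reads=1e7)
        stitched = stitch_enhancers([peak(0, 100), peak(5000, 5100)], stitch_distance=0)
        with pytest.warns(UserWarning, match="fewer than 3"):
            called = call_super_enhancers(stitched, t)
        assert not any(e.is_super for e in called)


class TestBroadDomains:
    def test_widths_1_to_100_selects_96_to_100(self):
        peaks = [peak(0, w, name=str(w)) for w in range(1, 101)]
        out = broad_domains(peaks, quantile=0.05)
        assert sorted(p.width for p in out.selected) == [96, 97, 98, 99, 100]
        assert out.width_cutoff == 96

    def test_200_distinct_widths_selects_exactly_10(self, rng):
        widths = rng.choice(np.arange(100, 100000), size=200, replace=False)
        peaks = [peak(0, int(w)) for w in widths]
        out = broad_domains(peaks, quantile=0.05)
        assert len(out.selected) == 10
        assert {p.width for p in out.selected} == set(sorted(widths)[-10:])

    def test_ties_at_cutoff_included(self):
        peaks = [peak(0, 10)] * 19 + [peak(0, 100)]
        out = broad_domains(peaks, quantile=0.05)
        assert [p.width for p in out.selected] == [100]
        out2 = broad_domains([peak(0, 100)] * 3 + [peak(0, 10)] * 17, quantile=0.05)
        assert len(out2.selected) == 3  # all ties at the cutoff width kept

    def test_all_equal_warns(self):
        with pytest.warns(UserWarning, match="every peak"):
            out = broad_domains([peak(0, 50)] * 10, quantile=0.05)
        assert len(out.selected) == 10

    def test_invalid_quantile(self):
        with pytest.raises(ValueError):
            broad_domains([peak(0, 10)], quantile=0.0)


class TestRegionTargets:
    def test_nearest_tss_within_distance(self):
        near = gene(10000, 30000, "+", gene_id="near")
        far = gene(200000, 230000, "+", gene_id="far")
        targets = assign_region_targets([gi(5000, 6000)], [near, far], max_distance=50000)
        assert targets == {"near"}

    def test_distance_boundary(self):
        g = gene(60000, 90000, "+", gene_id="g")  # tss = 60000
        # distance is measured from the region's last covered base (end - 1)
        assert assign_region_targets([gi(5000, 10001)], [g], max_distance=50000) == {"g"}
        assert assign_region_targets([gi(5000, 10000)], [g], max_distance=50000) == set()


class TestThreeWayPartition:
    def test_matches_set_algebra(self, rng):
        universe = [f"g{i}" for i in range(200)]
        a = {g for g in universe if rng.random() < 0.3}
        b = {g for g in universe if rng.random() < 0.3}
        c = {g for g in universe if rng.random() < 0.3}
        sectors, table, frac = three_way_partition(a, b, c)
        assert sum(sectors.values()) == len(a | b | c)
        only_a = a - b - c
        assert sectors.get("spreading", 0) == len(only_a)
        triple = a & b & c
        assert sectors.get("broad_h3k4me3&spreading&super_enhancer", 0) == len(triple)
        if a:
            assert frac == len(a & c) / len(a)
        assert len(table) == len(a | b | c)

    def test_empty_spreading_gives_nan_fraction(self):
        _, _, frac = three_way_partition(set(), {"x"}, {"y"})
        assert np.isnan(frac)
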