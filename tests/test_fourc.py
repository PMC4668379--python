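"""Read assignment, filtering, normalization, smoothing, domain calling and
feature-overlap scoring on toy and seeded synthetic profiles."""

import numpy as np
import pytest

import shox4c as s
from shox4c.fourc import (
    make_profile,
    running_mean_truncated,
)
from shox4c.fragmap import BLIND, INFORMATIVE


def brute_force_assign(reads, fmap):
    """Independent per-read linear containment scan."""
    counts = {c: np.zeros(len(f), dtype=int) for c, f in fmap.fragments.items()}
    unassigned = 0
    for r in reads:
        pos = r.start if r.strand == "+" else r.end - 1
        hit = False
        if r.chrom in fmap.fragments:
            for i, f in enumerate(fmap.fragments[r.chrom]):
                if f.interval.contains(pos):
                    counts[r.chrom][i] += 1
                    hit = True
                    break
        if not hit:
            unassigned += 1
    return counts, unassigned


class TestAssignReads:
    def test_no_reads(self, toy_map):
        a = s.assign_reads([], toy_map)
        assert a.n_reads == 0 and a.unassigned == 0
        assert all((c == 0).all() for c in a.counts.values())

    def test_single_plus_read_by_start(self, toy_map):
        a = s.assign_reads([s.AlignedRead("toy", 5, 20, "+")], toy_map)
        assert a.counts["toy"][1] == 1  # fragment [2,11) contains start 5

    def test_minus_read_assigned_by_five_prime_end(self, toy_map):
        # - read: 5' coordinate is end-1 = 12, in fragment [11,18)
        a = s.assign_reads([s.AlignedRead("toy", 5, 13, "-")], toy_map)
        assert a.counts["toy"][2] == 1

    def test_unknown_chromosome_counted_unassigned(self, toy_map):
        a = s.assign_reads([s.AlignedRead("chrZ", 0, 10)], toy_map)
        assert a.unassigned == 1 and a.assigned == 0

    def test_matches_brute_force_oracle(self, small_map):
        rng = np.random.default_rng(11)
        length = small_map.chrom_lengths["chr_s"]
        reads = [
            s.AlignedRead(
                "chr_s" if rng.random() > 0.02 else "chrZ",
                int(p), int(p) + 30,
                "+" if rng.random() < 0.5 else "-",
            )
            for p in rng.integers(0, length - 30, size=10_000)
        ]
        a = s.assign_reads(reads, small_map)
        counts, unassigned = brute_force_assign(reads, small_map)
        assert a.unassigned == unassigned
        assert (a.counts["chr_s"] == counts["chr_s"]).all()
        assert a.assigned + a.unassigned == len(reads)


class TestFilterCounts:
    def test_reads_in_blind_fragments_all_removed(self, small_map):
        blind_mids = [
            (f.interval.start + f.interval.end) // 2
            for f in small_map.fragments["chr_s"]
            if f.category == BLIND
        ][:50]
        reads = [s.AlignedRead("chr_s", m, m + 1) for m in blind_mids]
        a = s.assign_reads(reads, small_map)
        counts, report = s.filter_counts(a, small_map)
        assert counts.sum() == 0
        assert report.removed[BLIND] == len(reads)

    def test_too_short_fragment_reads_removed(self, toy_map_strict):
        # with min 40 bp every interior toy fragment is too short
        reads = [s.AlignedRead("toy", 5, 10)]
        a = s.assign_reads(reads, toy_map_strict)
        counts, report = s.filter_counts(a, toy_map_strict)
        assert counts.sum() == 0
        assert report.removed["too_short"] == 1

    def test_conservation_on_simulation(self, sim):
        a = s.assign_reads(sim.reads, sim.fmap)
        counts, report = s.filter_counts(a, sim.fmap)
        assert report.total == len(sim.reads)
        assert report.retained == counts.sum()

    def test_mismatched_map_rejected(self, toy_map, small_map):
        a = s.assign_reads([], toy_map)
        with pytest.raises(ValueError):
            s.filter_counts(a, small_map)


class TestMaskAndNormalize:
    def _profile(self, fmap, raw):
        lo, hi = fmap.fragend_range(fmap.chrom_order[0])
        vp_idx = (lo + hi) // 2
        fe = fmap.fragends[vp_idx]
        vp = s.locate_viewpoint(
            fmap, fe.fragment(fmap).interval
        )
        return make_profile(fmap, vp, np.asarray(raw))

    def test_k0_masks_only_viewpoint(self, small_map):
        p = self._profile(small_map, np.ones(small_map.n_fragends, dtype=int))
        s.mask_viewpoint(p, 0)
        assert p.masked.sum() == 1
        assert p.masked[p.viewpoint.global_index]

    def test_k_counts_each_side(self, small_map):
        p = self._profile(small_map, np.ones(small_map.n_fragends, dtype=int))
        s.mask_viewpoint(p, 2)
        assert p.masked.sum() == 5

    def test_normalization_sums_to_one_million(self, sim):
        unmasked = ~sim.profile.masked
        total = np.nansum(sim.profile.normalized[unmasked])
        assert total == pytest.approx(1e6, rel=1e-9)

    def test_simple_ratios(self, toy_map):
        p = self._profile(toy_map, [1, 3])
        # viewpoint masked: un-mask everything to test pure scaling
        p.masked[:] = False
        s.normalize(p)
        assert p.normalized.tolist() == [250_000.0, 750_000.0]

    def test_all_zero_counts_warns_and_zeroes(self, small_map):
        p = self._profile(small_map, np.zeros(small_map.n_fragends, dtype=int))
        s.normalize(p)
        assert np.nansum(p.normalized) == 0
        assert any("zero" in w for w in p.warnings)


class TestSmoothing:
    def test_window_must_be_odd(self, sim):
        with pytest.raises(ValueError):
            running_mean_truncated(np.arange(5.0), 4)
        with pytest.raises(ValueError):
            running_mean_truncated(np.arange(5.0), 0)

    def test_window_one_is_identity(self, sim):
        p = s.build_profile(
            sim.fmap, sim.reads[:5000], sim.viewpoint, mask_k=2, window_size=1
        )
        unmasked = ~p.masked
        np.testing.assert_allclose(p.smoothed[unmasked], p.normalized[unmasked])

    def test_constant_input_unchanged(self):
        out = running_mean_truncated(np.full(50, 3.7), 21)
        np.testing.assert_allclose(out, 3.7)

    def test_interior_matches_direct_mean_oracle(self, sim):
        p = sim.profile  # window 21
        chrom = p.cis_chrom
        lo, hi = p.fmap.fragend_range(chrom)
        idx = np.arange(lo, hi)
        idx = idx[~p.masked[idx]]
        vals = p.normalized[idx]
        h = 10
        for i in np.linspace(h, len(idx) - h - 1, 25, dtype=int):
            expected = vals[i - h : i + h + 1].mean()
            # cumulative-sum evaluation differs from the direct mean only by
            # float accumulation error
            assert p.smoothed[idx[i]] == pytest.approx(expected, rel=1e-9)

    def test_edges_truncate_to_available(self):
        v = np.arange(5.0)
        out = running_mean_truncated(v, 5)
        assert out[0] == pytest.approx(v[:3].mean())
        assert out[-1] == pytest.approx(v[2:].mean())

    def test_contraction(self, sim):
        p = sim.profile
        unmasked = ~p.masked
        assert np.nanmin(p.smoothed[unmasked]) >= np.nanmin(p.normalized[unmasked]) - 1e-9
        assert np.nanmax(p.smoothed[unmasked]) <= np.nanmax(p.normalized[unmasked]) + 1e-9


def rectangular_profile(small_map, plateau_halfwidth=50, level=50):
    """Step-function profile: high plateau around a central viewpoint fragend,
    zero elsewhere.  The plateau covers more than half the fragends so the
    median (quantile 0.5) threshold sits at the plateau level, not at zero."""
    n = small_map.n_fragends
    lo, hi = small_map.fragend_range("chr_s")
    vp_idx = (lo + hi) // 2
    fe = small_map.fragends[vp_idx]
    vp = s.locate_viewpoint(small_map, fe.fragment(small_map).interval)
    raw = np.zeros(n, dtype=int)
    raw[vp_idx - plateau_halfwidth : vp_idx + plateau_halfwidth + 1] = level
    p = make_profile(small_map, vp, raw)
    s.mask_viewpoint(p, 2)
    s.normalize(p)
    s.smooth(p, 1)  # window 1: keep the rectangle exact
    return p, vp_idx, plateau_halfwidth


class TestCallDomain:
    def test_rectangular_plateau_called_exactly(self, small_map):
        p, vp_idx, hw = rectangular_profile(small_map)
        call = s.call_domain(p, background_quantile=0.5, gap_tolerance=0)
        assert call.first_fragend == vp_idx - hw
        assert call.last_fragend == vp_idx + hw
        assert call.signal_fraction == pytest.approx(1.0)
        assert call.interval.contains(p.viewpoint.fragend.anchor_position)

    def test_gap_tolerance_bridges_single_dip(self, small_map):
        p, vp_idx, hw = rectangular_profile(small_map)
        # carve a one-fragend dip inside the plateau
        dip = vp_idx + hw // 2
        p.raw[dip] = 0
        s.normalize(p)
        s.smooth(p, 1)
        bridged = s.call_domain(p, background_quantile=0.5, gap_tolerance=1)
        assert bridged.last_fragend == vp_idx + hw
        cut = s.call_domain(p, background_quantile=0.5, gap_tolerance=0)
        assert cut.last_fragend == dip - 1

    def test_lower_quantile_never_shrinks_call(self, sim):
        prev_len = 0
        for q in (0.9, 0.75, 0.5, 0.25):
            call = s.call_domain(sim.profile, background_quantile=q, gap_tolerance=5)
            assert call.interval.length >= prev_len
            prev_len = call.interval.length

    def test_recovers_planted_domain(self, sim):
        call = s.call_domain(sim.profile)
        true = sim.truth.domain
        coverage = call.interval.intersection_length(true) / true.length
        assert coverage >= 0.9
        assert call.interval.length <= 1.2 * true.length

    def test_all_zero_profile_rejected(self, small_map):
        n = small_map.n_fragends
        lo, hi = small_map.fragend_range("chr_s")
        fe = small_map.fragends[(lo + hi) // 2]
        vp = s.locate_viewpoint(small_map, fe.fragment(small_map).interval)
        p = make_profile(small_map, vp, np.zeros(n, dtype=int))
        s.mask_viewpoint(p, 0)
        s.normalize(p)
        s.smooth(p, 21)
        with pytest.raises(ValueError, match="no signal"):
            s.call_domain(p)


class TestOverlapFeatures:
    def test_disjoint_feature_zero_overlap(self, sim):
        far = s.GenomicInterval("chr_other", 0, 1000)
        (o,) = s.overlap_features(sim.profile, None, [("far", far)])
        assert o.n_fragends_overlapped == 0
        assert o.mean_smoothed_signal is None and o.max_smoothed_signal is None
        assert not o.inside_domain

    def test_feature_equal_to_fragment_hits_its_fragend(self, toy_map):
        raw = np.array([4, 4])
        fe = toy_map.fragends[0]
        vp = s.locate_viewpoint(toy_map, fe.fragment(toy_map).interval)
        p = make_profile(toy_map, vp, raw)
        p.masked[:] = False
        s.normalize(p)
        s.smooth(p, 1)
        frag_iv = toy_map.fragends[1].fragment(toy_map).interval
        (o,) = s.overlap_features(p, None, [("f", frag_iv)])
        assert o.n_fragends_overlapped == 1
        assert o.max_smoothed_signal == pytest.approx(500_000.0)

    def test_peak_features_exceed_profile_median(self, sim):
        call = s.call_domain(sim.profile)
        overlaps = s.overlap_features(sim.profile, call, sim.features)
        unmasked = ~sim.profile.masked
        median = np.nanmedian(sim.profile.smoothed[unmasked])
        for o in overlaps:
            if o.name.startswith("peak"):
                assert o.max_smoothed_signal > median
                assert o.inside_domain

    def test_peaks_outscore_decoys(self, sim):
        overlaps = s.overlap_features(sim.profile, None, sim.features)
        peak_min = min(
            o.max_smoothed_signal for o in overlaps if o.name.startswith("peak")
        )
        decoy_max = max(
            o.max_smoothed_signal for o in overlaps if o.name.startswith("decoy")
        )
        assert peak_min > decoy_max


class TestPlantedPeakRecovery:
    def test_top_k_fragends_contain_all_planted_peaks(self, sim):
        # peak detection wants a narrow window: at window 3 each single-fragend
        # spike elevates exactly three windows, so the top 3*n_peaks smoothed
        # fragends must contain every planted peak fragend
        p = s.build_profile(
            sim.fmap, sim.reads, sim.viewpoint, mask_k=2, window_size=3
        )
        k = 3 * len(sim.model.peaks)
        sm = np.where(p.masked, -np.inf, np.nan_to_num(p.smoothed, nan=-np.inf))
        top = set(np.argsort(sm)[-k:])
        assert set(sim.truth.peak_fragends) <= top
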