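"""Nucleosome calling, peak classification, metaprofiles, differential
occupancy."""

import numpy as np
import pytest

from chromfate.genomic_io import GeneModel, GenomicInterval, Peak, SignalTrack
from chromfate.nucleosome import (
    call_nucleosomes,
    classify_peaks,
    differential_occupancy,
    metaprofile_point,
    metaprofile_scaled,
    shared_unique_signal,
)
from chromfate.simulate import _stamp_gaussians


def _track(values, bin_size=10, chrom="c"):
    values = np.asarray(values, dtype=float)
    return SignalTrack(
        bin_size, {chrom: len(values) * bin_size}, {chrom: values}
    )


def _bump_track(centers, length=20_000, amp=25.0, sigma=20.0, bg=0.5, bin_size=10):
    vals = bg + _stamp_gaussians(length, bin_size, centers, [amp] * len(centers), sigma)
    return _track(vals, bin_size)


class TestCallNucleosomes:
    def test_flat_track_yields_no_calls(self):
        with pytest.warns(UserWarning):
            assert call_nucleosomes(_track(np.full(500, 3.0))) == []

    def test_single_planted_bump_recovered_within_one_bin(self):
        track = _bump_track([5_000])
        calls = call_nucleosomes(track)
        assert len(calls) == 1
        assert abs(calls[0].center - 5_000) <= track.bin_size
        assert len(calls[0].interval) == 147

    def test_two_bumps_200bp_apart_give_two_calls(self):
        track = _bump_track([5_000, 5_200])
        calls = call_nucleosomes(track)
        assert len(calls) == 2
        assert not calls[0].interval.overlaps(calls[1].interval)

    def test_coarse_bins_rejected(self):
        with pytest.raises(ValueError):
            call_nucleosomes(_track(np.ones(100), bin_size=50))

    def test_scores_exceed_background(self):
        track = _bump_track([3_000, 9_000, 15_000])
        lam = float(track.data["c"].mean())
        for c in call_nucleosomes(track):
            assert c.occupancy_score > lam and c.q_like_score > 0


class TestClassifyPeaks:
    def _peak(self, summit, name="p"):
        return Peak(GenomicInterval("c", summit - 100, summit + 100), 100, name=name)

    def test_summit_at_call_center_is_nucleosomal(self):
        track = _bump_track([5_000])
        calls = call_nucleosomes(track)
        out = classify_peaks([self._peak(5_000)], calls)
        assert out.loc[0, "label"] == "nucleosomal"

    def test_summit_beyond_window_is_non_nucleosomal(self):
        track = _bump_track([5_000])
        calls = call_nucleosomes(track)
        edge = calls[0].interval.end
        out = classify_peaks([self._peak(edge + 73)], calls, window=73)
        assert out.loc[0, "label"] == "non-nucleosomal"
        out = classify_peaks([self._peak(edge + 72)], calls, window=73)
        assert out.loc[0, "label"] == "nucleosomal"

    def test_agrees_with_interval_overlap_oracle(self, rng):
        centers = np.arange(1_000, 19_000, 400)
        track = _bump_track(centers, length=20_000)
        calls = call_nucleosomes(track)
        peaks = [self._peak(int(s), f"p{i}")
                 for i, s in enumerate(rng.integers(200, 19_800, 80))]
        out = classify_peaks(peaks, calls, window=73)
        for peak, label in zip(peaks, out["label"]):
            lo, hi = peak.summit - 73, peak.summit + 73 + 1
            oracle = any(
                max(lo, c.interval.start) < min(hi, c.interval.end) for c in calls
            )
            assert (label == "nucleosomal") == oracle


class TestMetaprofilePoint:
    def test_constant_track_gives_constant_profile(self):
        track = _track(np.full(1_000, 4.0))
        prof = metaprofile_point(track, [("c", 3_000), ("c", 7_000)], 1000, 100)
        assert np.allclose(prof.matrix, 4.0)

    def test_unit_spike_lands_in_central_bin(self):
        vals = np.zeros(1_000)
        vals[500] = 1.0  # bp 5000-5010
        track = _track(vals)
        prof = metaprofile_point(track, [("c", 5_005)], flank=1000, n_bins=100)
        assert prof.matrix[0, 50] > 0
        assert prof.matrix[0, :49].sum() == 0

    def test_mean_equals_column_means(self, rng):
        track = _track(rng.uniform(0, 3, 2_000))
        anchors = [("c", int(a)) for a in rng.integers(2_000, 18_000, 15)]
        prof = metaprofile_point(track, anchors, 1000, 100)
        assert np.array_equal(prof.mean, prof.matrix.mean(axis=0))

    def test_minus_strand_anchor_is_flipped(self, rng):
        track = _track(rng.uniform(0, 3, 2_000))
        fwd = metaprofile_point(track, [("c", 9_000, "+")], 1000, 100)
        rev = metaprofile_point(track, [("c", 9_000, "-")], 1000, 100)
        assert np.array_equal(rev.matrix[0], fwd.matrix[0][::-1])

    def test_out_of_range_flank_zero_padded_and_flagged(self):
        track = _track(np.full(100, 2.0))  # 1 kb chromosome
        prof = metaprofile_point(track, [("c", 100)], flank=1000, n_bins=100)
        assert prof.n_clipped == 1
        assert prof.matrix[0, 0] == 0.0

    def test_empty_anchor_list_rejected(self):
        with pytest.raises(ValueError):
            metaprofile_point(_track(np.ones(10)), [], 100, 10)

    def test_planted_bump_amplitude_recovered(self):
        centers = [4_000, 8_000, 12_000]
        track = _bump_track(centers, length=16_000, amp=25.0, bg=0.0)
        # 10-bp profile bins so the bump tip is not averaged down
        prof = metaprofile_point(track, [("c", c) for c in centers], 1000, 200)
        assert prof.mean[100] == pytest.approx(25.0, rel=0.1)


class TestMetaprofileScaled:
    def _genes(self, spans):
        return [
            GeneModel(f"g{i}", GenomicInterval("c", s, e, strand))
            for i, (s, e, strand) in enumerate(spans)
        ]

    def test_constant_track_gives_flat_profile(self):
        track = _track(np.full(2_000, 3.0))
        genes = self._genes([(4_000, 7_000, "+"), (9_000, 15_000, "-")])
        prof = metaprofile_scaled(track, genes)
        assert np.allclose(prof.matrix, 3.0)

    def test_body_restricted_signal(self):
        vals = np.zeros(2_000)
        vals[400:700] = 1.0  # signal exactly on gene body 4000-7000
        track = _track(vals)
        prof = metaprofile_scaled(track, self._genes([(4_000, 7_000, "+")]))
        body = prof.matrix[0, 50:150]
        flanks = np.concatenate([prof.matrix[0, :50], prof.matrix[0, 150:]])
        assert np.allclose(body, 1.0)
        assert np.allclose(flanks, 0.0)

    def test_strand_reversal_mirrors_profile(self, rng):
        track = _track(rng.uniform(0, 2, 3_000))
        plus = metaprofile_scaled(track, self._genes([(8_000, 13_000, "+")]))
        minus = metaprofile_scaled(track, self._genes([(8_000, 13_000, "-")]))
        assert np.allclose(minus.matrix[0], plus.matrix[0][::-1])

    def test_short_gene_interpolated_and_flagged(self):
        track = _track(np.full(2_000, 1.0))
        prof = metaprofile_scaled(track, self._genes([(5_000, 5_050, "+")]))
        assert prof.metadata["short_genes"] == ["g0"]
        assert np.allclose(prof.matrix[0, 50:150], 1.0)


class TestSharedUnique:
    def _peaks(self, summits, prefix="p"):
        return [
            Peak(GenomicInterval("c", s - 100, s + 100), 100, name=f"{prefix}{i}")
            for i, s in enumerate(summits)
        ]

    def test_same_set_is_all_shared(self):
        a = self._peaks([3_000, 6_000, 9_000])
        track = _track(np.ones(2_000))
        with pytest.warns(UserWarning):
            out = shared_unique_signal(a, a, track)
        assert out["n_shared"] == 3 and out["n_unique"] == 0
        assert out["unique"] is None

    def test_disjoint_sets_are_all_unique(self):
        a = self._peaks([3_000, 6_000])
        b = self._peaks([12_000], "q")
        track = _track(np.ones(2_000))
        with pytest.warns(UserWarning):
            out = shared_unique_signal(a, b, track)
        assert out["n_unique"] == 2 and out["shared"] is None

    def test_double_signal_at_shared_peaks_gives_ratio_two(self):
        summits = list(range(3_000, 18_000, 1_500))
        a = self._peaks(summits)
        b = self._peaks(summits[: len(summits) // 2], "q")  # first half shared
        amps = [2.0 if i < len(summits) // 2 else 1.0 for i in range(len(summits))]
        vals = _stamp_gaussians(20_000, 10, summits, amps, 50.0)
        out = shared_unique_signal(a, b, _track(vals))
        assert out["shared_unique_ratio"] == pytest.approx(2.0, rel=0.1)


class TestDifferentialOccupancy:
    def _regions(self, centers, half=150):
        return [GenomicInterval("c", c - half, c + half) for c in centers]

    def test_identical_tracks_give_zero_log2fc(self):
        track = _bump_track([3_000, 6_000, 9_000], length=12_000)
        diff = differential_occupancy(track, track, self._regions([3_000, 6_000, 9_000]))
        assert np.allclose(diff.log2fc, 0.0)

    def test_global_scaling_absorbed_by_size_factors(self):
        mock = _bump_track([3_000, 6_000, 9_000], length=12_000)
        treat = _track(2.0 * mock.data["c"])
        diff = differential_occupancy(treat, mock, self._regions([3_000, 6_000, 9_000]))
        assert np.allclose(diff.log2fc, 0.0, atol=1e-9)

    def test_swap_negates_log2fc(self):
        rng = np.random.default_rng(2)
        mock = _track(rng.uniform(1, 5, 1_200))
        treat = _track(rng.uniform(1, 5, 1_200))
        regions = self._regions(list(range(1_000, 11_000, 1_000)))
        fwd = differential_occupancy(treat, mock, regions).log2fc
        rev = differential_occupancy(mock, treat, regions).log2fc
        assert np.allclose(fwd, -rev, atol=1e-9)

    def test_median_ratio_normalisation_centers_at_one(self):
        rng = np.random.default_rng(3)
        mock = _track(rng.uniform(1, 5, 2_000))
        treat = _track(3.0 * rng.uniform(1, 5, 2_000))
        # odd region count: the paired median-of-ratios identity is exact
        regions = self._regions(list(range(1_000, 19_500, 500)))
        assert len(regions) % 2 == 1
        diff = differential_occupancy(treat, mock, regions)
        nt = diff.table["norm_treat"].to_numpy()
        nm = diff.table["norm_mock"].to_numpy()
        geo = np.sqrt(nt * nm)
        assert np.median(nt / geo) == pytest.approx(1.0, abs=1e-9)
        assert np.median(nm / geo) == pytest.approx(1.0, abs=1e-9)

    def test_empty_regions_rejected(self):
        track = _bump_track([3_000])
        with pytest.raises(ValueError):
            differential_occupancy(track, track, [])

    def test_planted_halving_recovered(self):
        centers = np.arange(1_000, 199_000, 200)
        targets = np.zeros(len(centers), bool)
        targets[::10] = True
        amp_m = np.full(len(centers), 40.0)
        amp_t = np.where(targets, 20.0, 40.0)
        base = 0.1
        mock = _track(base + _stamp_gaussians(200_000, 10, centers, amp_m, 20.0))
        treat = _track(base + _stamp_gaussians(200_000, 10, centers, amp_t, 20.0))
        diff = differential_occupancy(treat, mock, self._regions(centers))
        assert diff.log2fc[targets].mean() == pytest.approx(-1.0, abs=0.1)
        assert abs(diff.log2fc[~targets].mean()) < 0.1
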