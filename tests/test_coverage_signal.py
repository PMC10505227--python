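import numpy as np
import pytest

from breakspan.coverage_signal import (
    MetaProfile,
    compute_coverage,
    depth_normalize,
    metaprofile,
    poisson_enrichment,
    profile_halfwidth,
    site_enrichment,
    top_n_sites,
)
from breakspan.formats_io import ReadInterval, SignalTrack
from breakspan.genome_sites import CutSite


def uniform_track(value, n_bins=1000, bin_size=10, contig="c1"):
    return SignalTrack(bin_size, {contig: np.full(n_bins, float(value))})


class TestComputeCoverage:
    def test_single_read_fills_one_bin(self):
        track = compute_coverage([ReadInterval("c1", 0, 10)], {"c1": 100}, 10)
        assert track.values["c1"][0] == 1.0

    def test_read_split_across_bins(self):
        track = compute_coverage([ReadInterval("c1", 5, 15)], {"c1": 100}, 10)
        np.testing.assert_array_equal(track.values["c1"][:2], [0.5, 0.5])

    def test_no_reads_gives_zero_track(self):
        track = compute_coverage([], {"c1": 100}, 10)
        assert track.total_signal == 0.0

    def test_unknown_contig_named_in_error(self):
        with pytest.raises(ValueError, match="c9"):
            compute_coverage([ReadInterval("c9", 0, 10)], {"c1": 100}, 10)

    def test_read_base_conservation(self, small_sim):
        _, ref, _, reads, _ = small_sim
        track = compute_coverage(reads, ref.lengths, 10)
        total_bases = sum(len(r) for r in reads)
        assert track.total_signal * track.bin_size == pytest.approx(total_bases)


class TestDepthNormalize:
    def test_scaling_factor(self):
        track = SignalTrack(10, {"c1": np.array([50.0])})
        (out,) = depth_normalize([track], 1e6)
        assert out.values["c1"][0] == pytest.approx(1e6)

    def test_two_tracks_equal_totals(self):
        t1 = SignalTrack(10, {"c1": np.array([10.0])})
        t2 = SignalTrack(10, {"c1": np.array([40.0])})
        o1, o2 = depth_normalize([t1, t2], 1e6)
        assert o1.total_signal == pytest.approx(o2.total_signal, rel=1e-6)

    def test_zero_track_rejected(self):
        with pytest.raises(ValueError):
            depth_normalize([SignalTrack(10, {"c1": np.zeros(5)})], 1e6)

    def test_idempotent(self):
        track = SignalTrack(10, {"c1": np.array([3.0, 7.0])})
        (once,) = depth_normalize([track], 1e6)
        (twice,) = depth_normalize([once], 1e6)
        np.testing.assert_allclose(once.values["c1"], twice.values["c1"])


class TestPoissonEnrichment:
    def test_zero_treatment_scores_zero(self):
        t = SignalTrack(10, {"c1": np.zeros(5)})
        c = SignalTrack(10, {"c1": np.ones(5)})
        out = poisson_enrichment(t, c, lambda_floor=1.0)
        np.testing.assert_array_equal(out.values["c1"], np.zeros(5))

    def test_hand_computed_tail(self):
        # t=3 against lambda=1: -log10(1 - e^-1 (1 + 1 + 1/2)) = 1.0953
        t = SignalTrack(10, {"c1": np.array([3.0])})
        c = SignalTrack(10, {"c1": np.array([1.0])})
        out = poisson_enrichment(t, c, lambda_floor=1.0)
        expected = -np.log10(1 - np.exp(-1) * 2.5)
        assert out.values["c1"][0] == pytest.approx(expected, abs=1e-6)
        assert out.values["c1"][0] == pytest.approx(1.0953, abs=1e-4)

    @pytest.mark.parametrize("control", [0.5, 1.0, 5.0])
    def test_score_monotone_in_treatment(self, control):
        tvals = np.arange(0, 51, dtype=float)
        t = SignalTrack(10, {"c1": tvals})
        c = SignalTrack(10, {"c1": np.full_like(tvals, control)})
        out = poisson_enrichment(t, c, lambda_floor=min(control, 1.0))
        assert np.all(np.diff(out.values["c1"]) >= 0)

    def test_binning_mismatch_rejected(self):
        t = SignalTrack(10, {"c1": np.zeros(5)})
        c = SignalTrack(20, {"c1": np.zeros(5)})
        with pytest.raises(ValueError):
            poisson_enrichment(t, c, 1.0)

    def test_default_floor_is_mean_control(self):
        t = SignalTrack(10, {"c1": np.array([5.0, 5.0])})
        c = SignalTrack(10, {"c1": np.array([0.0, 4.0])})
        out = poisson_enrichment(t, c)  # floor = mean control = 2.0
        ref = poisson_enrichment(t, c, lambda_floor=2.0)
        np.testing.assert_allclose(out.values["c1"], ref.values["c1"])


class TestSiteEnrichment:
    def test_uniform_track_window_arithmetic(self):
        track = uniform_track(2.0)
        site = CutSite("c1", 4997, site_id="s")  # center [5000, 5002)
        enr = site_enrichment(track, [site], flank=1000)
        # window spans 2*flank + 2 nt of the cut center
        assert enr["s"] == pytest.approx(2.0 * 2002)

    def test_zero_track_zero_enrichment(self):
        track = SignalTrack(10, {"c1": np.zeros(1000)})
        enr = site_enrichment(track, [CutSite("c1", 4997, site_id="s")], 1000)
        assert enr["s"] == 0.0

    def test_linearity(self, small_sim):
        _, ref, sites, reads, _ = small_sim
        track = compute_coverage(reads, ref.lengths, 10)
        doubled = track.copy()
        for c in doubled.values:
            doubled.values[c] *= 2
        e1 = site_enrichment(track, sites, 1000)
        e2 = site_enrichment(doubled, sites, 1000)
        for sid in e1:
            assert e2[sid] == pytest.approx(2 * e1[sid])


class TestTopN:
    SITES = [
        CutSite("c1", 100, site_id="s1"),
        CutSite("c1", 5000, site_id="s2"),
        CutSite("c1", 9000, site_id="s3"),
    ]

    def test_descending_order(self):
        top = top_n_sites({"s1": 10, "s2": 5, "s3": 7}, self.SITES, 2)
        assert [s.site_id for s in top] == ["s1", "s3"]

    def test_tie_broken_by_coordinate(self):
        top = top_n_sites({"s1": 5, "s2": 5, "s3": 0}, self.SITES, 1)
        assert top[0].site_id == "s1"

    def test_n_larger_than_sites(self):
        top = top_n_sites({"s1": 1, "s2": 2, "s3": 3}, self.SITES, 10)
        assert len(top) == 3

    def test_stable_under_input_permutation(self):
        enr = {"s1": 3.0, "s2": 3.0, "s3": 9.0}
        a = top_n_sites(enr, self.SITES, 3, contig_order={"c1": 0})
        b = top_n_sites(enr, self.SITES[::-1], 3, contig_order={"c1": 0})
        assert [s.site_id for s in a] == [s.site_id for s in b]


class TestMetaprofile:
    def test_uniform_track_flat_profile(self):
        track = uniform_track(3.0)
        site = CutSite("c1", 4997, site_id="s")
        prof = metaprofile(track, [site], flank=500, bin_size=10)
        np.testing.assert_allclose(prof.values, 3.0)

    def test_two_identical_sites_average_to_one(self):
        track = uniform_track(1.5)
        sites = [CutSite("c1", 2997, site_id="a"), CutSite("c1", 6997, site_id="b")]
        prof2 = metaprofile(track, sites, 500, 10)
        prof1 = metaprofile(track, sites[:1], 500, 10)
        np.testing.assert_allclose(prof2.values, prof1.values)

    def test_truncated_sites_dropped_and_counted(self):
        track = uniform_track(1.0, n_bins=100)  # contig 1000 bp
        sites = [CutSite("c1", 10, site_id="edge"), CutSite("c1", 497, site_id="mid")]
        prof = metaprofile(track, sites, flank=400, bin_size=10)
        assert prof.n_sites == 1 and prof.n_dropped == 1

    def test_all_sites_dropped_is_error(self):
        track = uniform_track(1.0, n_bins=10)
        with pytest.raises(ValueError, match="dropped"):
            metaprofile(track, [CutSite("c1", 10, site_id="e")], 400, 10)

    def test_flank_must_be_bin_multiple(self):
        with pytest.raises(ValueError):
            metaprofile(uniform_track(1.0), [CutSite("c1", 4997)], 505, 10)


class TestProfileHalfwidth:
    def test_all_mass_in_first_bins(self):
        values = np.zeros(200)
        values[99] = 5.0  # last bin left of center
        values[100] = 5.0  # first bin right of center
        prof = MetaProfile(1000, 10, values, n_sites=1)
        assert profile_halfwidth(prof) == (10.0, 10.0)

    def test_uniform_one_sided_mass(self):
        values = np.zeros(200)
        values[100:] = 1.0  # uniform over 1000 bp on the right
        prof = MetaProfile(1000, 10, values, n_sites=1)
        left, right = profile_halfwidth(prof, 0.9)
        assert left == 0.0
        assert abs(right - 900.0) <= 10.0

    def test_zero_profile_rejected(self):
        prof = MetaProfile(100, 10, np.zeros(20), n_sites=1)
        with pytest.raises(ValueError):
            profile_halfwidth(prof)
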