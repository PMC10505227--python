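import numpy as np
import pytest

from breakspan.coverage_signal import compute_coverage, site_enrichment
from breakspan.formats_io import ReadInterval
from breakspan.genome_sites import CutSite
from breakspan.span_ratio import (
    SpanClassification,
    bootstrap_ks_test,
    classify_read,
    continuous_ks,
    histogram_ks,
    span_ratio_per_site,
    span_ratio_vector,
)

SITE = CutSite("c1", 100, site_id="s")  # center [103, 105)


def brute_force_label(read, site, max_dist=5):
    """Per-base oracle: enumerate covered bases and center bases."""
    if read.contig != site.contig:
        return "excluded"
    cs, ce = site.center_interval
    bases = set(range(read.start, read.end))
    center = set(range(cs, ce))
    if bases & center:
        return "spanning"
    gap = min(abs(b - c) for b in bases for c in center) - 1
    return "not_spanning" if gap <= max_dist else "excluded"


class TestClassifyRead:
    @pytest.mark.parametrize(
        "start,end,label",
        [
            (80, 103, "not_spanning"),  # abutting on the left, gap 0
            (100, 110, "spanning"),  # overlaps both center bases
            (110, 130, "not_spanning"),  # gap 5 == max_dist
            (111, 130, "excluded"),  # gap 6
            (103, 105, "spanning"),  # exactly the center
            (104, 120, "spanning"),  # one shared base
            (105, 120, "not_spanning"),  # abutting on the right
        ],
    )
    def test_worked_examples(self, start, end, label):
        assert classify_read(ReadInterval("c1", start, end), SITE) == label

    def test_other_contig_excluded(self):
        assert classify_read(ReadInterval("c2", 100, 110), SITE) == "excluded"

    def test_total_partition_matches_brute_force(self):
        rng = np.random.default_rng(3)
        for _ in range(2000):
            start = int(rng.integers(0, 220))
            length = int(rng.integers(1, 40))
            read = ReadInterval("c1", start, start + length)
            assert classify_read(read, SITE) == brute_force_label(read, SITE)


class TestSpanRatioPerSite:
    READS = [
        ReadInterval("c1", 100, 110),  # spanning
        ReadInterval("c1", 80, 103),  # not spanning
        ReadInterval("c1", 105, 120),  # not spanning
        ReadInterval("c1", 200, 220),  # excluded
        ReadInterval("c2", 100, 110),  # other contig
    ]

    def test_counts_and_ratio(self):
        cls = span_ratio_per_site(self.READS, SITE)
        assert (cls.n_span, cls.n_nospan) == (1, 2)
        assert cls.ratio == pytest.approx(1 / 3)

    def test_no_qualifying_reads_drops_site(self):
        assert span_ratio_per_site([ReadInterval("c1", 200, 220)], SITE) is None

    def test_all_spanning_ratio_one(self):
        reads = [ReadInterval("c1", 100, 110)] * 4
        assert span_ratio_per_site(reads, SITE).ratio == 1.0

    def test_undefined_ratio_raises(self):
        with pytest.raises(ValueError):
            SpanClassification("s", 0, 0).ratio

    def test_abutting_reads_with_infinite_window_give_zero_ratio(self):
        reads = [ReadInterval("c1", 80, 103), ReadInterval("c1", 105, 130)]
        cls = span_ratio_per_site(reads, SITE, max_dist=np.inf)
        assert cls.ratio == 0.0


class TestSpanRatioVector:
    def test_vector_follows_ranking_and_drop_rules(self, small_sim):
        cfg, ref, sites, reads, _ = small_sim
        track = compute_coverage(reads, ref.lengths, 10)
        enr = site_enrichment(track, sites, 1000)
        vec, classes = span_ratio_vector(reads, sites, enr, top_sites=20)
        assert len(vec) == len(classes) <= 20
        assert np.all((vec >= 0) & (vec <= 1))

    def test_too_few_sites_is_error(self):
        reads = [ReadInterval("c1", 100, 110)]
        sites = [SITE]
        with pytest.raises(ValueError, match="fewer than 2"):
            span_ratio_vector(reads, sites, {"s": 1.0}, top_sites=5)


class TestHistogramKS:
    def test_identical_vectors(self):
        v = [0.1, 0.4, 0.9]
        assert histogram_ks(v, v) == 0.0

    def test_fully_separated_vectors(self):
        a = [0.1, 0.1, 0.1, 0.1]
        b = [0.9, 0.9, 0.9, 0.9]
        assert histogram_ks(a, b, n_bins=10) == 1.0

    def test_symmetric(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a, b = rng.random(30), rng.random(40)
            assert histogram_ks(a, b) == histogram_ks(b, a)

    def test_value_one_falls_in_last_bin(self):
        assert histogram_ks([1.0], [1.0]) == 0.0

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            histogram_ks([], [0.5])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            histogram_ks([1.5], [0.5])


class TestBootstrapKS:
    def test_identical_vectors_give_p_one(self):
        v = np.linspace(0, 1, 20)
        res = bootstrap_ks_test(v, v, B=200, seed=0)
        assert res.observed_ks == 0.0 and res.p_value == 1.0

    def test_p_invariant_under_swap(self):
        rng = np.random.default_rng(2)
        a, b = rng.random(30), rng.random(50)
        r1 = bootstrap_ks_test(a, b, B=500, seed=7)
        r2 = bootstrap_ks_test(b, a, B=500, seed=7)
        assert r1.p_value == r2.p_value and r1.observed_ks == r2.observed_ks

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        a, b = rng.random(30), rng.random(30)
        r1 = bootstrap_ks_test(a, b, seed=11)
        r2 = bootstrap_ks_test(a, b, seed=11)
        assert r1.p_value == r2.p_value
        np.testing.assert_array_equal(r1.bootstrap_ks, r2.bootstrap_ks)

    def test_p_is_fraction_of_bootstrap_at_least_observed(self):
        rng = np.random.default_rng(5)
        a, b = rng.beta(2, 5, 40), rng.beta(5, 2, 40)
        res = bootstrap_ks_test(a, b, B=400, seed=3)
        assert res.p_value == pytest.approx(
            np.mean(res.bootstrap_ks >= res.observed_ks - 1e-12)
        )

    def test_plus_one_variant(self):
        v = np.linspace(0, 1, 20)
        res = bootstrap_ks_test(v, v, B=99, seed=0, plus_one=True)
        assert res.p_value == pytest.approx(1.0)

    @pytest.mark.parametrize("bad", [([0.5], [0.1, 0.2]), ([0.1, 0.2], [0.3])])
    def test_short_vectors_rejected(self, bad):
        with pytest.raises(ValueError):
            bootstrap_ks_test(*bad)

    def test_zero_bootstraps_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ks_test([0.1, 0.2], [0.3, 0.4], B=0)

    def test_separation_monotone_in_effect_size(self):
        # as experiment B's ratios drift from A's, median p is non-increasing
        rng = np.random.default_rng(6)
        medians = []
        for shift in (0.0, 0.2, 0.4):
            ps = []
            for i in range(20):
                a = rng.beta(2, 2, 50)
                b = np.clip(rng.beta(2, 2, 50) + shift, 0, 1)
                ps.append(bootstrap_ks_test(a, b, B=300, seed=100 + i).p_value)
            medians.append(np.median(ps))
        assert medians[0] >= medians[1] >= medians[2]

    def test_conclusion_stable_across_bin_counts(self):
        rng = np.random.default_rng(8)
        a, b = rng.beta(1, 9, 50), rng.beta(9, 1, 50)
        for n_bins in (10, 20, 50):
            res = bootstrap_ks_test(a, b, B=500, n_bins=n_bins, seed=9)
            assert res.p_value < 0.01

    def test_continuous_ks_cross_check(self):
        # with many bins, the binned statistic approaches the classical one
        rng = np.random.default_rng(9)
        a, b = rng.random(200), rng.random(200)
        binned = histogram_ks(a, b, n_bins=1000)
        assert binned == pytest.approx(continuous_ks(a, b), abs=0.01)
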