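"""Breakpoint-spanning read classification and the bootstrap KS comparison.

A read near a cut site either *spans* the 2-nt cut-center region (any
overlap), sits *not spanning* within ``max_dist`` nt of it without
crossing, or is *excluded*. The per-site span ratio

    ratio = n_span / (n_span + n_nospan)

is low where breaks persist (reads abut but never cross the cut) and high
where sites are repaired or uncut. Two experiments' span-ratio vectors are
compared with a resampling null: merge, re-partition at random into the
original group sizes, histogram each partition on [0, 1], and take the
maximum CDF distance (a binned Kolmogorov-Smirnov statistic); the p-value
is the fraction of resampled statistics at least as large as the observed
one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Literal, Optional, Sequence, Tuple

import numpy as np

from .formats_io import ReadInterval
from .genome_sites import CutSite

SpanLabel = Literal["spanning", "not_spanning", "excluded"]

DEFAULT_MAX_DIST = 5
DEFAULT_N_BINS = 20
DEFAULT_B = 1000


@dataclass(frozen=True)
class SpanClassification:
    """Per-site spanning / non-spanning counts."""

    site_id: str
    n_span: int
    n_nospan: int

    def __post_init__(self) -> None:
        if self.n_span < 0 or self.n_nospan < 0:
            raise ValueError("counts must be >= 0")

    @property
    def ratio(self) -> float:
        total = self.n_span + self.n_nospan
        if total == 0:
            raise ValueError("span ratio undefined with no qualifying reads")
        return self.n_span / total


@dataclass
class BootstrapKSResult:
    """Observed binned-KS statistic against its resampling null."""

    observed_ks: float
    bootstrap_ks: np.ndarray
    p_value: float
    B: int
    n_bins: int
    seed: Optional[int]

    def to_dict(self) -> dict:
        return {
            "observed_ks": self.observed_ks,
            "p_value": self.p_value,
            "B": self.B,
            "n_bins": self.n_bins,
            "seed": self.seed,
        }


def classify_read(
    read: ReadInterval, site: CutSite, max_dist: float = DEFAULT_MAX_DIST
) -> SpanLabel:
    """Label one read relative to one site's 2-nt cut center.

    spanning: >= 1 bp overlap with the center interval. not_spanning: no
    overlap and gap <= max_dist, where gap = center_start - read_end for a
    read left of the center and read_start - center_end on the right
    (half-open arithmetic: an abutting read has gap 0). Anything else,
    including a different contig, is excluded.
    """
    if read.contig != site.contig:
        return "excluded"
    cs, ce = site.center_interval
    if read.start < ce and read.end > cs:
        return "spanning"
    gap = cs - read.end if read.end <= cs else read.start - ce
    return "not_spanning" if gap <= max_dist else "excluded"


def span_counts(
    reads: Sequence[ReadInterval],
    site: CutSite,
    max_dist: float = DEFAULT_MAX_DIST,
) -> Tuple[int, int]:
    """Vectorized (n_span, n_nospan) over all reads on the site's contig."""
    starts = np.array([r.start for r in reads if r.contig == site.contig])
    if starts.size == 0:
        return 0, 0
    ends = np.array([r.end for r in reads if r.contig == site.contig])
    cs, ce = site.center_interval
    spanning = (starts < ce) & (ends > cs)
    gap = np.where(ends <= cs, cs - ends, starts - ce)
    nospan = ~spanning & (gap <= max_dist)
    return int(spanning.sum()), int(nospan.sum())


def span_ratio_per_site(
    reads: Sequence[ReadInterval],
    site: CutSite,
    max_dist: float = DEFAULT_MAX_DIST,
    min_reads: int = 1,
) -> Optional[SpanClassification]:
    """Counts for one site, or None when fewer than ``min_reads`` qualify."""
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    n_span, n_nospan = span_counts(reads, site, max_dist)
    if n_span + n_nospan < min_reads:
        return None
    return SpanClassification(site.site_id, n_span, n_nospan)


def span_ratio_vector(
    reads: Sequence[ReadInterval],
    sites: Sequence[CutSite],
    enrichment: Dict[str, float],
    top_sites: int = 50,
    max_dist: float = DEFAULT_MAX_DIST,
    min_reads: int = 1,
) -> Tuple[np.ndarray, List[SpanClassification]]:
    """Span ratios for the top-``top_sites`` sites by enrichment.

    Sites with fewer than ``min_reads`` qualifying reads are dropped; the
    vector is in ranking order. Raises when fewer than 2 sites survive.
    """
    from .coverage_signal import top_n_sites

    ranked = top_n_sites(enrichment, list(sites), top_sites)
    classifications = [
        c
        for site in ranked
        if (c := span_ratio_per_site(reads, site, max_dist, min_reads)) is not None
    ]
    if len(classifications) < 2:
        raise ValueError(
            "fewer than 2 sites with qualifying reads; cannot compare distributions"
        )
    return np.array([c.ratio for c in classifications]), classifications


def _bin_indices(values: np.ndarray, n_bins: int) -> np.ndarray:
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    # left-closed bins, right edge of the last bin inclusive (histogram rule)
    idx = np.searchsorted(edges, values, side="right") - 1
    return np.minimum(idx, n_bins - 1)


def histogram_ks(
    vec_a: Sequence[float], vec_b: Sequence[float], n_bins: int = DEFAULT_N_BINS
) -> float:
    """Max CDF distance between the two vectors' normalized histograms on [0, 1]."""
    a = np.asarray(vec_a, dtype=float)
    b = np.asarray(vec_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both vectors must be non-empty")
    for v in (a, b):
        if np.any((v < 0) | (v > 1)):
            raise ValueError("span ratios must lie in [0, 1]")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    cdf_a = np.cumsum(np.bincount(_bin_indices(a, n_bins), minlength=n_bins) / a.size)
    cdf_b = np.cumsum(np.bincount(_bin_indices(b, n_bins), minlength=n_bins) / b.size)
    return float(np.abs(cdf_a - cdf_b).max())


def bootstrap_ks_test(
    vec_a: Sequence[float],
    vec_b: Sequence[float],
    B: int = DEFAULT_B,
    n_bins: int = DEFAULT_N_BINS,
    seed: Optional[int] = None,
    plus_one: bool = False,
) -> BootstrapKSResult:
    """Resampling null for the binned KS distance between two ratio vectors.

    The merged vector is partitioned without replacement into groups of the
    two original sizes, B times; p = fraction of partition KS statistics >=
    the observed one (``plus_one`` switches to the (k+1)/(B+1) estimate).
    The merged vector is sorted and the smaller group drawn first, so the
    result is invariant to swapping the inputs. Deterministic given seed.
    """
    a = np.asarray(vec_a, dtype=float)
    b = np.asarray(vec_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 ratios per experiment")
    if B < 1:
        raise ValueError("B must be >= 1")
    observed = histogram_ks(a, b, n_bins)

    merged = np.sort(np.concatenate([a, b]))
    n1, n2 = sorted((a.size, b.size))
    n = n1 + n2
    idx = _bin_indices(merged, n_bins)

    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(np.arange(n), (B, 1)), axis=1)
    g1 = idx[perms[:, :n1]]
    g2 = idx[perms[:, n1:]]
    offsets = np.arange(B)[:, None] * n_bins
    h1 = np.bincount((g1 + offsets).ravel(), minlength=B * n_bins).reshape(B, n_bins)
    h2 = np.bincount((g2 + offsets).ravel(), minlength=B * n_bins).reshape(B, n_bins)
    cdf1 = np.cumsum(h1 / n1, axis=1)
    cdf2 = np.cumsum(h2 / n2, axis=1)
    boot = np.abs(cdf1 - cdf2).max(axis=1)

    k = int(np.sum(boot >= observed - 1e-12))
    p = (k + 1) / (B + 1) if plus_one else k / B
    return BootstrapKSResult(observed, boot, float(p), B, n_bins, seed)


def continuous_ks(vec_a: Sequence[float], vec_b: Sequence[float]) -> float:
    """Unbinned two-sample KS distance (cross-check, not the primary statistic)."""
    from scipy import stats

    return float(stats.ks_2samp(np.asarray(vec_a), np.asarray(vec_b)).statistic)
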