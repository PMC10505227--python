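"""Coverage tracks, enrichment scoring, site ranking and metaprofiles.

Reads are turned into binned coverage, depth-normalized so libraries are
equivalent in total signal, optionally scored against a control with an
upper-tail Poisson statistic (the treatment/control track comparison used
downstream of peak calling), aggregated per cut site over a +/-1-kb window,
ranked, and averaged into cut-centered metaprofiles with a signal-mass
width summary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .formats_io import ReadInterval, SignalTrack
from .genome_sites import CutSite, site_window

DEFAULT_BIN_SIZE = 10
DEFAULT_FLANK = 1000


@dataclass
class MetaProfile:
    """Mean signal per offset bin around cut centers (negative = upstream)."""

    flank: int
    bin_size: int
    values: np.ndarray  # length 2*flank/bin_size
    n_sites: int
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != 2 * self.flank // self.bin_size:
            raise ValueError("profile length must be 2*flank/bin_size")
        if np.any(self.values < 0):
            raise ValueError("profile values must be >= 0")

    @property
    def offsets(self) -> np.ndarray:
        """Bin-center offsets relative to the cut center midpoint."""
        edges = np.arange(-self.flank, self.flank + 1, self.bin_size)
        return (edges[:-1] + edges[1:]) / 2.0


def compute_coverage(
    reads: Iterable[ReadInterval],
    contig_lengths: Dict[str, int],
    bin_size: int = DEFAULT_BIN_SIZE,
) -> SignalTrack:
    """Binned coverage: read-bases overlapping each bin, divided by bin_size."""
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    diffs = {
        contig: np.zeros(length + 1, dtype=np.int64)
        for contig, length in contig_lengths.items()
    }
    for read in reads:
        if read.contig not in diffs:
            raise ValueError(f"read on unknown contig {read.contig!r}")
        length = contig_lengths[read.contig]
        start = min(read.start, length)
        end = min(read.end, length)
        if end > start:
            diffs[read.contig][start] += 1
            diffs[read.contig][end] -= 1
    values: Dict[str, np.ndarray] = {}
    for contig, length in contig_lengths.items():
        depth = np.cumsum(diffs[contig][:-1])
        n_bins = -(-length // bin_size)
        padded = np.zeros(n_bins * bin_size, dtype=np.int64)
        padded[:length] = depth
        values[contig] = padded.reshape(n_bins, bin_size).sum(axis=1) / bin_size
    return SignalTrack(bin_size, values, dict(contig_lengths))


def depth_normalize(
    tracks: Sequence[SignalTrack], target_total: float = 1e6
) -> List[SignalTrack]:
    """Scale each track so its total signal equals ``target_total``."""
    if target_total <= 0:
        raise ValueError("target_total must be > 0")
    out = []
    for track in tracks:
        total = track.total_signal
        if total <= 0:
            raise ValueError("cannot depth-normalize a zero-total track")
        scaled = track.copy()
        factor = target_total / total
        for contig in scaled.values:
            scaled.values[contig] = scaled.values[contig] * factor
        out.append(scaled)
    return out


def poisson_enrichment(
    treatment: SignalTrack,
    control: SignalTrack,
    lambda_floor: Optional[float] = None,
) -> SignalTrack:
    """Per-bin -log10 P(X >= t), X ~ Poisson(max(control, lambda_floor)).

    The treatment value is rounded to the nearest integer for the discrete
    upper tail: P(X >= t) = 1 - CDF(t - 1), so t = 0 scores 0.
    ``lambda_floor`` defaults to the genome-wide mean control value and
    keeps scores finite where the control is empty.
    """
    if treatment.bin_size != control.bin_size:
        raise ValueError("treatment and control must share bin_size")
    if set(treatment.values) != set(control.values):
        raise ValueError("treatment and control must cover the same contigs")
    if lambda_floor is None:
        n_bins = sum(len(v) for v in control.values.values())
        lambda_floor = control.total_signal / n_bins if n_bins else 0.0
    if lambda_floor <= 0:
        raise ValueError("lambda_floor must be > 0")
    out: Dict[str, np.ndarray] = {}
    for contig, tvals in treatment.values.items():
        cvals = control.values[contig]
        if len(tvals) != len(cvals):
            raise ValueError(f"binning mismatch on contig {contig!r}")
        lam = np.maximum(cvals, lambda_floor)
        t_int = np.rint(tvals)
        # upper tail P(X >= t) = sf(t - 1); logsf keeps extreme bins finite
        score = -stats.poisson.logsf(t_int - 1, lam) / np.log(10.0)
        out[contig] = np.maximum(score, 0.0)
    return SignalTrack(treatment.bin_size, out, dict(treatment.contig_lengths))


def site_enrichment(
    track: SignalTrack,
    sites: Sequence[CutSite],
    flank: int = DEFAULT_FLANK,
) -> Dict[str, float]:
    """Total signal (bin value x bp, partial bins pro-rated) in each site window."""
    if flank <= 0:
        raise ValueError("flank must be > 0")
    result: Dict[str, float] = {}
    for site in sites:
        if site.contig not in track.values:
            raise ValueError(f"site {site.site_id!r} on unknown contig {site.contig!r}")
        clen = track.contig_lengths.get(site.contig)
        start, end = site_window(site, flank, clen)
        result[site.site_id] = float(track.base_values(site.contig, start, end).sum())
    return result


def top_n_sites(
    enrichment: Dict[str, float],
    sites: Sequence[CutSite],
    n: int,
    contig_order: Optional[Dict[str, int]] = None,
) -> List[CutSite]:
    """Top-n sites by enrichment, ties broken by (contig order, start)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if contig_order is None:
        contig_order = {}
        for site in sites:
            contig_order.setdefault(site.contig, len(contig_order))
    ranked = sorted(
        sites,
        key=lambda s: (
            -enrichment[s.site_id],
            contig_order.get(s.contig, len(contig_order)),
            s.motif_start,
        ),
    )
    return ranked[: min(n, len(ranked))]


def metaprofile(
    track: SignalTrack,
    sites: Sequence[CutSite],
    flank: int = DEFAULT_FLANK,
    bin_size: int = DEFAULT_BIN_SIZE,
) -> MetaProfile:
    """Mean signal over [center - flank, center + flank) across sites.

    The window is centered on the midpoint of the 2-nt cut center; sites
    whose window is truncated by a contig end are dropped (counted in
    ``n_dropped``).
    """
    if flank % bin_size != 0:
        raise ValueError("flank must be a multiple of bin_size")
    n_bins = 2 * flank // bin_size
    acc = np.zeros(n_bins)
    used = 0
    dropped = 0
    for site in sites:
        mid = site.center_mid
        start, end = mid - flank, mid + flank
        clen = track.contig_lengths.get(
            site.contig, len(track.values[site.contig]) * track.bin_size
        )
        if start < 0 or end > clen:
            dropped += 1
            continue
        base = track.base_values(site.contig, start, end)
        acc += base.reshape(n_bins, bin_size).mean(axis=1)
        used += 1
    if used == 0:
        raise ValueError("all sites dropped (windows truncated by contig ends)")
    return MetaProfile(flank, bin_size, acc / used, n_sites=used, n_dropped=dropped)


def profile_halfwidth(
    profile: MetaProfile, mass_fraction: float = 0.9
) -> Tuple[float, float]:
    """One-sided signal-mass radii of a metaprofile, in bp.

    On each side of offset 0 independently: the smallest distance d such
    that bins within [0, d] hold at least ``mass_fraction`` of that side's
    total signal. A side with zero signal reports width 0.
    """
    if not (0.0 < mass_fraction < 1.0):
        raise ValueError("mass_fraction must lie in (0, 1)")
    total = profile.values.sum()
    if total <= 0:
        raise ValueError("cannot measure widths of an all-zero profile")
    half = len(profile.values) // 2
    left = profile.values[:half][::-1]  # walking upstream from the center
    right = profile.values[half:]

    def one_side(side: np.ndarray) -> float:
        s = side.sum()
        if s <= 0:
            return 0.0
        cum = np.cumsum(side) / s
        k = int(np.argmax(cum >= mass_fraction))
        return float((k + 1) * profile.bin_size)

    return one_side(left), one_side(right)
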