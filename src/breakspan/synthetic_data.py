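"""Synthetic ChIP-read generator with cut-site ground truth.

Emulates the signal structure of sequencing protein-bound cleavage products
around nuclease-induced double-strand breaks:

* planted recognition motifs with log-normal per-site cutting efficiency
  (long-tailed site ranking);
* a **released** regime — short fragments whose break-proximal (inner) edge
  lies within ``release_halfwidth`` of the cut center, emulating products
  recovered when the end-bound kinase is catalytically blocked and signal
  stays within ~200 bp of the break;
* a **spreading** regime — inner edges at half-normal distances with scale
  ``spreading_halfwidth``, emulating dispersal of signal up to ~1 kb and
  beyond when the kinase is active;
* a configurable fraction of break-derived reads that span the central 2-nt
  overhang region (repaired or uncut sites);
* break-independent background: promoter-like peaks placed away from cut
  sites, plus uniform noise reads.

Every read is a single interval (one alignment record); mate pairs,
sequencing errors and duplicates are not modeled.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from .formats_io import ReadInterval, ReferenceSequence
from .genome_sites import ASISI_MOTIF, CutSite


class ConfigError(ValueError):
    """An invalid or infeasible simulation configuration."""


@dataclass
class SimulationConfig:
    """Parameters of one simulated ChIP experiment.

    Defaults describe a 2 x 1-Mb genome with 200 sites and the released
    regime's short-fragment geometry; rates are per-site Poisson means and
    reads/kb for background.
    """

    seed: int = 0
    n_contigs: int = 2
    contig_length: int = 1_000_000
    n_sites: int = 200
    min_site_spacing: int = 4000
    motif: str = ASISI_MOTIF
    # per-site relative cutting efficiency ~ LogNormal, mean-normalized to 1
    efficiency_mu_log: float = 0.0
    efficiency_sigma_log: float = 1.0
    regime: str = "released"  # or "spreading"
    fragment_length_mean: float = 80.0
    fragment_length_sd: float = 25.0
    fragment_length_min: float = 20.0
    release_halfwidth: float = 200.0  # W_r: max inner-edge distance, released
    spreading_halfwidth: float = 400.0  # W_s: half-normal inner-edge scale
    spanning_fraction: float = 0.1  # f_span
    reads_per_site_mean: float = 100.0
    background_rate: float = 0.5  # uniform noise reads per kb
    n_promoters: int = 20
    promoter_reads_mean: float = 50.0
    promoter_spread: float = 200.0  # sd of read midpoints around a promoter
    occupancy_scale: float = 1.0  # time-course emulation multiplier

    def validate(self) -> None:
        if self.seed < 0:
            raise ConfigError("seed must be non-negative")
        if self.n_contigs < 1 or self.contig_length < 100:
            raise ConfigError("need at least one contig of >= 100 bp")
        if self.n_sites < 0:
            raise ConfigError("n_sites must be >= 0")
        if self.regime not in ("released", "spreading"):
            raise ConfigError("regime must be 'released' or 'spreading'")
        if not (0.0 <= self.spanning_fraction <= 1.0):
            raise ConfigError("spanning_fraction must lie in [0, 1]")
        if not (0.0 <= self.occupancy_scale <= 1.0):
            raise ConfigError("occupancy_scale must lie in [0, 1]")
        for name in (
            "reads_per_site_mean",
            "background_rate",
            "promoter_reads_mean",
            "release_halfwidth",
            "spreading_halfwidth",
            "efficiency_sigma_log",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.fragment_length_min < 1 or self.fragment_length_mean < self.fragment_length_min:
            raise ConfigError("fragment length model must allow lengths >= fragment_length_min >= 1")
        halfwidth = (
            self.release_halfwidth if self.regime == "released" else self.spreading_halfwidth
        )
        if self.min_site_spacing <= 2 * (halfwidth + self.fragment_length_mean):
            raise ConfigError(
                "min_site_spacing must exceed 2*(placement halfwidth + mean fragment length)"
            )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        cfg = cls(**d)
        cfg.validate()
        return cfg


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth per planted site: efficiency and emitted read counts."""

    site_id: str
    efficiency: float
    n_reads: int
    n_spanning: int

    def __post_init__(self) -> None:
        if self.n_spanning > self.n_reads:
            raise ValueError("n_spanning cannot exceed n_reads")


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def make_genome(config: SimulationConfig) -> Tuple[ReferenceSequence, List[CutSite]]:
    """Random genome with exactly ``n_sites`` planted motifs.

    Background sequence is locally re-drawn until no spurious plus-strand
    motif occurrence exists, so a motif scan returns exactly the planted
    sites. Deterministic given the config seed.
    """
    config.validate()
    rng = _rng(config, 1)
    motif = config.motif.upper()
    m = len(motif)
    margin = max(config.min_site_spacing // 2, 200)

    # distribute sites across contigs as evenly as possible
    per_contig = [config.n_sites // config.n_contigs] * config.n_contigs
    for i in range(config.n_sites % config.n_contigs):
        per_contig[i] += 1

    contigs: Dict[str, str] = {}
    sites: List[CutSite] = []
    for ci in range(config.n_contigs):
        name = f"chr{ci + 1}"
        k = per_contig[ci]
        usable = config.contig_length - 2 * margin - m
        slack = usable - (k - 1) * config.min_site_spacing if k > 0 else usable
        if k > 0 and slack < 0:
            raise ConfigError(
                f"contig of {config.contig_length} bp cannot host {k} sites "
                f"at spacing {config.min_site_spacing}"
            )
        seq = _BASES[rng.integers(0, 4, config.contig_length)].copy()
        positions = []
        if k > 0:
            offsets = np.sort(rng.integers(0, slack + 1, size=k))
            positions = [
                int(margin + offsets[j] + j * config.min_site_spacing)
                for j in range(k)
            ]
            motif_arr = np.frombuffer(motif.encode(), dtype="S1")
            for pos in positions:
                seq[pos : pos + m] = motif_arr
        _scrub_spurious(seq, motif, positions, rng)
        contigs[name] = seq.tobytes().decode()
        for pos in positions:
            sites.append(CutSite(name, pos, m, site_id=f"site_{len(sites) + 1}"))
    return ReferenceSequence(contigs), sites


def _scrub_spurious(
    seq: np.ndarray, motif: str, planted: List[int], rng: np.random.Generator
) -> None:
    """Re-draw bases of non-planted motif occurrences until none remain."""
    m = len(motif)
    planted_set = set(planted)
    protected = np.zeros(len(seq), dtype=bool)
    for pos in planted:
        protected[pos : pos + m] = True
    for _ in range(200):
        text = seq.tobytes().decode()
        spurious = []
        start = text.find(motif)
        while start != -1:
            if start not in planted_set:
                spurious.append(start)
            start = text.find(motif, start + 1)
        if not spurious:
            return
        for occ in spurious:
            span = np.arange(occ, occ + m)
            editable = span[~protected[span]]
            seq[editable] = _BASES[rng.integers(0, 4, len(editable))]
    raise RuntimeError("failed to scrub spurious motif occurrences")


def _fragment_lengths(
    n: int, config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Truncated-normal fragment lengths (>= fragment_length_min), as ints."""
    out = np.empty(n)
    remaining = np.arange(n)
    while remaining.size:
        draw = rng.normal(config.fragment_length_mean, config.fragment_length_sd, remaining.size)
        ok = draw >= config.fragment_length_min
        out[remaining[ok]] = draw[ok]
        remaining = remaining[~ok]
    return np.maximum(np.rint(out).astype(int), int(config.fragment_length_min))


def simulate_chip_reads(
    ref: ReferenceSequence,
    sites: List[CutSite],
    config: SimulationConfig,
) -> Tuple[List[ReadInterval], List[TruthRecord]]:
    """Emit ChIP reads around cut sites plus background, with ground truth.

    Per site i: read count ~ Poisson(reads_per_site_mean * e_i *
    occupancy_scale) with mean-normalized log-normal efficiency e_i. Each
    break-derived read spans the 2-nt cut center with probability
    ``spanning_fraction``; otherwise it lies entirely on one side with its
    inner edge at Uniform[0, W_r] (released) or |Normal(0, W_s)|
    (spreading) from the center boundary, never overlapping the center.
    Background: uniform noise reads plus promoter-like peaks. Deterministic
    given the config seed.
    """
    config.validate()
    rng = _rng(config, 2)
    lengths = ref.lengths
    reads: List[ReadInterval] = []
    truth: List[TruthRecord] = []

    n_sites = len(sites)
    if n_sites:
        eff = rng.lognormal(config.efficiency_mu_log, config.efficiency_sigma_log, n_sites)
        eff = eff / eff.mean()
    else:
        eff = np.empty(0)

    for i, site in enumerate(sites):
        clen = lengths[site.contig]
        lam = config.reads_per_site_mean * eff[i] * config.occupancy_scale
        n_reads = int(rng.poisson(lam))
        frag = _fragment_lengths(n_reads, config, rng)
        spans = rng.random(n_reads) < config.spanning_fraction
        cs, ce = site.center_interval
        n_spanning = 0
        for j in range(n_reads):
            L = int(frag[j])
            if spans[j]:
                # start anywhere that guarantees >= 1 bp overlap with the center
                start = int(rng.integers(cs - L + 1, ce))
                end = start + L
                n_spanning += 1
            else:
                if config.regime == "released":
                    d = int(np.rint(rng.uniform(0.0, config.release_halfwidth)))
                else:
                    d = int(np.rint(abs(rng.normal(0.0, config.spreading_halfwidth))))
                if rng.random() < 0.5:  # left of the break
                    end = cs - d
                    start = end - L
                else:
                    start = ce + d
                    end = start + L
            start = max(0, start)
            end = min(clen, end)
            if end <= start:
                continue
            reads.append(
                ReadInterval(site.contig, start, end, f"{site.site_id}_r{j + 1}", "+")
            )
        truth.append(TruthRecord(site.site_id, float(eff[i]), n_reads, n_spanning))

    _emit_background(reads, sites, lengths, config, rng)
    return reads, truth


def _emit_background(
    reads: List[ReadInterval],
    sites: List[CutSite],
    lengths: Dict[str, int],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> None:
    contig_names = list(lengths)
    clens = np.array([lengths[c] for c in contig_names], dtype=float)
    total_kb = clens.sum() / 1000.0
    weights = clens / clens.sum()

    # uniform noise
    n_noise = int(rng.poisson(config.background_rate * total_kb))
    if n_noise:
        which = rng.choice(len(contig_names), size=n_noise, p=weights)
        frag = _fragment_lengths(n_noise, config, rng)
        for j in range(n_noise):
            contig = contig_names[which[j]]
            clen = lengths[contig]
            start = int(rng.integers(0, clen))
            end = min(clen, start + int(frag[j]))
            if end > start:
                reads.append(ReadInterval(contig, start, end, f"bg_{j + 1}", "+"))

    # promoter-like break-independent peaks, kept >= 2 kb from any cut center
    site_centers: Dict[str, np.ndarray] = {}
    for site in sites:
        site_centers.setdefault(site.contig, [])
    for site in sites:
        site_centers[site.contig].append(site.center_mid)
    site_centers = {c: np.array(v) for c, v in site_centers.items()}

    for p in range(config.n_promoters):
        for _ in range(1000):
            contig = contig_names[int(rng.choice(len(contig_names), p=weights))]
            clen = lengths[contig]
            locus = int(rng.integers(2000, clen - 2000))
            centers = site_centers.get(contig)
            if centers is None or centers.size == 0 or np.abs(centers - locus).min() >= 2000:
                break
        else:
            raise ConfigError("could not place promoters >= 2 kb from all cut sites")
        n_pr = int(rng.poisson(config.promoter_reads_mean))
        if n_pr == 0:
            continue
        mids = rng.normal(locus, config.promoter_spread, n_pr)
        frag = _fragment_lengths(n_pr, config, rng)
        for j in range(n_pr):
            start = int(np.rint(mids[j] - frag[j] / 2))
            end = start + int(frag[j])
            start = max(0, start)
            end = min(lengths[contig], end)
            if end > start:
                reads.append(
                    ReadInterval(contig, start, end, f"prom{p + 1}_r{j + 1}", "+")
                )


TRUTH_COLUMNS = ["site_id", "efficiency", "n_reads", "n_spanning"]


def write_truth(truth: List[TruthRecord], path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        [(t.site_id, t.efficiency, t.n_reads, t.n_spanning) for t in truth],
        columns=TRUTH_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_truth(path: str | os.PathLike) -> List[TruthRecord]:
    df = pd.read_csv(path, sep="\t")
    missing = set(TRUTH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"truth table missing columns: {sorted(missing)}")
    return [
        TruthRecord(str(r.site_id), float(r.efficiency), int(r.n_reads), int(r.n_spanning))
        for r in df.itertuples(index=False)
    ]
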