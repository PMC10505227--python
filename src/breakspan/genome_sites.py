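"""Cut-site annotation: motif scanning and break geometry.

The default motif is the AsiSI recognition sequence GCGATCGC, which is
cleaved between the T and C of the central AT dinucleotide (GCGAT/CGC) on
each strand, leaving 2-nt 3' overhangs. The two overhang bases — the "AT
region", motif offsets 3 and 4 — define the cut center that every
downstream analysis (span classification, windows, metaprofiles) keys on.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

from .formats_io import ParseError, ReadInterval, ReferenceSequence

ASISI_MOTIF = "GCGATCGC"


@dataclass(frozen=True)
class CutSite:
    """A cut locus: the motif interval and the 2-nt cut-center interval."""

    contig: str
    motif_start: int
    motif_length: int = 8
    site_id: str = ""
    center_start: int = -1  # filled from motif geometry when negative
    center_end: int = -1

    def __post_init__(self) -> None:
        if self.motif_start < 0 or self.motif_length < 4:
            raise ValueError("motif_start must be >= 0 and motif_length >= 4")
        if self.center_start < 0:
            # middle 2 nt of the motif: offsets 3..5 for an 8-mer
            object.__setattr__(
                self, "center_start", self.motif_start + self.motif_length // 2 - 1
            )
            object.__setattr__(self, "center_end", self.center_start + 2)
        if self.center_end - self.center_start != 2:
            raise ValueError("center_interval must have length 2")
        if not (
            self.motif_start < self.center_start
            and self.center_end < self.motif_start + self.motif_length
        ):
            raise ValueError("center_interval must lie strictly inside the motif")

    @property
    def motif_interval(self) -> Tuple[int, int]:
        return (self.motif_start, self.motif_start + self.motif_length)

    @property
    def center_interval(self) -> Tuple[int, int]:
        return (self.center_start, self.center_end)

    @property
    def center_mid(self) -> int:
        """Midpoint position between the two cut-center bases."""
        return self.center_start + 1


def scan_motif(
    ref: ReferenceSequence, motif: str = ASISI_MOTIF
) -> List[CutSite]:
    """All plus-strand occurrences of ``motif``, in (contig, start) order.

    Overlapping occurrences are reported; windows containing N never match.
    For a reverse-complement-palindromic motif such as GCGATCGC a single
    plus-strand pass is complete.
    """
    motif = motif.upper()
    if not motif:
        raise ValueError("motif must be non-empty")
    if len(motif) < 4:
        raise ValueError("motif must be at least 4 bp")
    if set(motif) - set("ACGT"):
        raise ValueError("motif must be over {A, C, G, T} (no ambiguity codes)")
    sites: List[CutSite] = []
    for contig in ref:
        seq = ref[contig]
        pos = seq.find(motif)
        while pos != -1:
            sites.append(
                CutSite(
                    contig,
                    pos,
                    len(motif),
                    site_id=f"site_{len(sites) + 1}",
                )
            )
            pos = seq.find(motif, pos + 1)
    return sites


def site_window(
    site: CutSite, flank: int, contig_length: Optional[int] = None
) -> Tuple[int, int]:
    """Window [center_start - flank, center_end + flank), clipped to the contig."""
    if flank <= 0:
        raise ValueError("flank must be > 0")
    start = max(0, site.center_start - flank)
    end = site.center_end + flank
    if contig_length is not None:
        end = min(end, contig_length)
    return (start, end)


def write_sites_bed(sites: List[CutSite], path: str | os.PathLike) -> None:
    """BED6 + thickStart/thickEnd: motif interval as the span, cut center as thick."""
    with open(path, "w") as fh:
        for site in sites:
            ms, me = site.motif_interval
            cs, ce = site.center_interval
            fh.write(
                f"{site.contig}\t{ms}\t{me}\t{site.site_id}\t0\t+\t{cs}\t{ce}\n"
            )


def read_sites_bed(path: str | os.PathLike) -> List[CutSite]:
    """Read cut sites back from BED.

    With 8 columns, thickStart/thickEnd give the explicit 2-nt cut center
    (required for externally supplied target lists, e.g. Cas9 guides);
    otherwise the center defaults to the middle 2 nt of the record span.
    """
    path = os.fspath(path)
    sites: List[CutSite] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{line_no}: BED line has fewer than 3 columns")
            contig = fields[0]
            start, end = int(fields[1]), int(fields[2])
            if end <= start:
                raise ParseError(f"{path}:{line_no}: invalid interval [{start}, {end})")
            name = fields[3] if len(fields) > 3 else f"site_{len(sites) + 1}"
            if len(fields) >= 8:
                cs, ce = int(fields[6]), int(fields[7])
                sites.append(
                    CutSite(contig, start, end - start, name, cs, ce)
                )
            else:
                sites.append(CutSite(contig, start, end - start, name))
    return sites


def sites_to_intervals(sites: List[CutSite]) -> List[ReadInterval]:
    return [
        ReadInterval(s.contig, *s.motif_interval, name=s.site_id, strand="+")
        for s in sites
    ]


def contig_order_index(ref_or_lengths) -> Dict[str, int]:
    """Stable contig ordering used for deterministic tie-breaking."""
    if hasattr(ref_or_lengths, "contigs"):
        names = list(ref_or_lengths.contigs)
    else:
        names = list(ref_or_lengths)
    return {name: i for i, name in enumerate(names)}
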