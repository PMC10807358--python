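"""Ets core-consensus scanning and summit-window site counting.

Ets-family transcription factors recognize a 4-bp GGAA/T core.  The scanner
reports every forward-strand occurrence of GGAA/GGAT as a + site and every
occurrence of TTCC/ATCC (the reverse complements) as a - site; overlapping
occurrences are all reported and N never matches.  No position-weight
matrix is applied: the 4-mer core is the operational definition of an Ets
site here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

from .intervals import Peak
from .io import GenomeSequence

logger = logging.getLogger(__name__)

FORWARD_CORES = ("GGAA", "GGAT")
REVERSE_CORES = ("TTCC", "ATCC")  # forward-strand text of a - strand core
ALL_CORES = frozenset(FORWARD_CORES + REVERSE_CORES)
CORE_LEN = 4

DEFAULT_SUMMIT_WINDOW = 200
DEFAULT_MIN_SITES = 2


@dataclass(frozen=True)
class MotifSite:
    """One core occurrence; ``matched_text`` is always the forward-strand 4-mer."""

    chrom: str
    start: int
    strand: str
    matched_text: str


@dataclass(frozen=True)
class SummitSiteCount:
    peak: Peak
    n_sites: int
    window_bp: int
    clipped: bool = False


def scan_ets_sites(sequence: str, chrom: str = "", offset: int = 0) -> list[MotifSite]:
    """All Ets-core occurrences in ``sequence``, positions shifted by ``offset``.

    Both strands are scanned on the forward text; a site's ``start`` is the
    0-based genomic position of the first base of the 4-mer.
    """
    seq = sequence.upper()
    sites: list[MotifSite] = []
    for i in range(len(seq) - CORE_LEN + 1):
        word = seq[i : i + CORE_LEN]
        if word in FORWARD_CORES:
            sites.append(MotifSite(chrom, offset + i, "+", word))
        elif word in REVERSE_CORES:
            sites.append(MotifSite(chrom, offset + i, "-", word))
    return sites


def count_sites_near_summits(
    peaks: Sequence[Peak],
    genome: GenomeSequence,
    window_bp: int = DEFAULT_SUMMIT_WINDOW,
) -> list[SummitSiteCount]:
    """Count Ets cores whose start lies within ``window_bp`` of each peak summit.

    The counted span is [summit - window_bp, summit + window_bp] inclusive
    (site *start* positions).  The scanned genome slice is extended by 3 bp
    so cores straddling the window edge are still seen; windows clipped at
    a chromosome end are counted over the clipped region and flagged.
    """
    out: list[SummitSiteCount] = []
    n_midpoint = 0
    for peak in peaks:
        if peak.summit is None:
            n_midpoint += 1
        s = peak.summit_or_midpoint()
        chrom_len = len(genome[peak.chrom])
        lo = s - window_bp
        hi = s + window_bp + CORE_LEN  # exclusive slice end; last start = s + window_bp
        clipped = lo < 0 or hi > chrom_len
        lo_c, hi_c = max(0, lo), min(chrom_len, hi)
        sites = scan_ets_sites(genome.slice(peak.chrom, lo_c, hi_c), peak.chrom, offset=lo_c)
        n = sum(1 for site in sites if s - window_bp <= site.start <= s + window_bp)
        out.append(SummitSiteCount(peak, n, window_bp, clipped))
    if n_midpoint:
        logger.info("count_sites_near_summits: midpoint fallback used for %d peak(s)", n_midpoint)
    return out


def has_multiple_sites(count: SummitSiteCount, min_sites: int = DEFAULT_MIN_SITES) -> bool:
    """True iff the summit window holds at least ``min_sites`` Ets cores."""
    return count.n_sites >= min_sites
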