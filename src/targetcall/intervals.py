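"""Interval algebra on 0-based half-open genomic coordinates.

Every coordinate in the package follows the BED convention: ``start`` is
0-based inclusive, ``end`` is exclusive, so ``length = end - start`` and two
intervals overlap iff they share at least one base.  Book-ended intervals
([0,100) and [100,200)) do not overlap but have gap 0, matching
bedtools-style semantics.  Chromosome names are compared by exact string
equality; no ``chr`` aliasing is ever attempted.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from intervaltree import IntervalTree

STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic span ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.chrom}")
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"unknown strand symbol {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def expand(self, pad: int) -> "GenomicInterval":
        """Pad both ends by ``pad`` bp, clipped at 0."""
        return GenomicInterval(self.chrom, max(0, self.start - pad), self.end + pad, self.strand)

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class Peak:
    """A called peak with an optional summit.

    ``summit_offset`` is the narrowPeak column-10 convention: bp from
    ``interval.start``, or ``None`` when the source format carried the -1
    sentinel.  Summit-dependent operations fall back to the interval
    midpoint in that case.
    """

    interval: GenomicInterval
    summit_offset: Optional[int] = None
    score: float = 0.0
    replicate_id: str = ""
    assay: str = "chip"
    cluster: Optional[str] = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.assay not in ("chip", "atac"):
            raise ValueError(f"unknown assay {self.assay!r}")
        if self.score < 0:
            raise ValueError("peak score must be non-negative")
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < self.interval.length
        ):
            raise ValueError(
                f"summit offset {self.summit_offset} outside peak "
                f"{self.interval} (length {self.interval.length})"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def summit(self) -> Optional[int]:
        """Absolute summit position, or None when absent."""
        if self.summit_offset is None:
            return None
        return self.interval.start + self.summit_offset

    def summit_or_midpoint(self) -> int:
        """Summit if present, else the floor midpoint of the interval."""
        s = self.summit
        return self.interval.midpoint if s is None else s


@dataclass(frozen=True)
class GeneModel:
    """Gene span with strand-derived transcription start site."""

    gene_id: str
    name: str
    interval: GenomicInterval
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -, got {self.strand!r}")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def tss(self) -> int:
        """TSS: span start on +, last base of the span on -."""
        return self.interval.start if self.strand == "+" else self.interval.end - 1


def intervals_overlap(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two half-open intervals share >= 1 bp on the same chromosome."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def interval_gap(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bp strictly between two same-chromosome intervals (0 if they touch)."""
    if a.chrom != b.chrom:
        raise ValueError(f"interval_gap on different chromosomes: {a.chrom} vs {b.chrom}")
    return max(0, a.start - b.end, b.start - a.end)


def overlap_query(
    query: Sequence[GenomicInterval], subject: Sequence[GenomicInterval]
) -> list[list[int]]:
    """For each query interval, indices of subject intervals overlapping it.

    Output is identical to the quadratic all-pairs check; subject indices
    are returned sorted.
    """
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for i, iv in enumerate(subject):
        trees[iv.chrom].addi(iv.start, iv.end, i)
    out: list[list[int]] = []
    for q in query:
        tree = trees.get(q.chrom)
        if tree is None:
            out.append([])
        else:
            out.append(sorted(hit.data for hit in tree.overlap(q.start, q.end)))
    return out


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping (not merely book-ended) intervals per chromosome."""
    by_chrom: dict[str, list[GenomicInterval]] = defaultdict(list)
    for iv in intervals:
        by_chrom[iv.chrom].append(iv)
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda iv: (iv.start, iv.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start < cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged


def total_bp(intervals: Iterable[GenomicInterval]) -> int:
    return sum(iv.length for iv in merge_intervals(intervals))


def validate_chromosome_names(
    referenced: Iterable[str], known: Iterable[str], what: str = "input"
) -> None:
    """Raise if any referenced chromosome is absent from the known set.

    Matching is exact string equality on purpose: silently reconciling
    'chr2L' with '2L' is how integrations go quietly wrong.
    """
    missing = sorted(set(referenced) - set(known))
    if missing:
        raise ValueError(
            f"{what} references chromosomes absent from the genome/annotation: "
            + ", ".join(missing)
        )
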