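"""Peak-to-gene assignment, peak location classes, and replicate statistics.

A peak is assigned to every gene whose span lies within a fixed edge-to-edge
distance of the peak interval (default 2 kb, boundary inclusive); the
assignment is deliberately many-to-many.  Peak location is classified from
the summit with precedence TSS-proximal > genic > intergenic.  Replicate
agreement is reported directionally (percent of A's peaks hitting B) plus a
symmetric base-pair Jaccard, because directional overlap percentages are
not symmetric for peak sets of different depth.
"""

from __future__ import annotations

import bisect
import logging
import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .intervals import (
    GeneModel,
    GenomicInterval,
    Peak,
    interval_gap,
    intervals_overlap,
    merge_intervals,
)
from .io import GenomeSequence

logger = logging.getLogger(__name__)

DEFAULT_GENE_WINDOW = 2000
DEFAULT_TSS_WINDOW = 1000
DEFAULT_SUMMIT_SEQ_WIDTH = 500

LOCATION_CATEGORIES = ("tss_proximal", "genic", "intergenic")


@dataclass(frozen=True)
class PeakGeneAssignment:
    peak: Peak
    gene_id: str
    gap_bp: int
    relation: str  # overlapping | upstream_of_tss | downstream


@dataclass(frozen=True)
class PeakLocationClass:
    peak: Peak
    category: str


@dataclass
class ReplicateOverlapReport:
    """Directional overlap percentages and symmetric bp Jaccard between peak sets."""

    names: list[str]
    fraction: pd.DataFrame  # percent of row-set peaks overlapping >=1 column-set peak
    jaccard: pd.DataFrame  # merged-bp Jaccard, symmetric
    undefined: set[str]  # names of empty peak sets (fractions reported as NaN)


def _gene_tree(genes: Sequence[GeneModel], pad: int) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for i, g in enumerate(genes):
        # pad by window + 1 so a gap of exactly `window` still intersects
        trees[g.chrom].addi(max(0, g.interval.start - pad - 1), g.interval.end + pad + 1, i)
    return trees


def _relation(peak: Peak, gene: GeneModel) -> str:
    if intervals_overlap(peak.interval, gene.interval):
        return "overlapping"
    peak_before = peak.interval.end <= gene.interval.start
    on_tss_side = peak_before if gene.strand == "+" else not peak_before
    return "upstream_of_tss" if on_tss_side else "downstream"


def assign_peaks_to_genes(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    window_bp: int = DEFAULT_GENE_WINDOW,
) -> list[PeakGeneAssignment]:
    """All (peak, gene) pairs with edge-to-edge gap <= window_bp (inclusive)."""
    if window_bp < 0:
        raise ValueError("window_bp must be non-negative")
    trees = _gene_tree(genes, window_bp)
    assignments: list[PeakGeneAssignment] = []
    n_orphan_chrom = 0
    for peak in peaks:
        tree = trees.get(peak.chrom)
        if tree is None:
            n_orphan_chrom += 1
            continue
        for hit in sorted(tree.overlap(peak.interval.start, peak.interval.end), key=lambda h: h.data):
            gene = genes[hit.data]
            gap = interval_gap(peak.interval, gene.interval)
            if gap <= window_bp:
                assignments.append(PeakGeneAssignment(peak, gene.gene_id, gap, _relation(peak, gene)))
    if n_orphan_chrom:
        logger.info("assign_peaks_to_genes: %d peak(s) on chromosomes absent from the gene table", n_orphan_chrom)
    return assignments


def classify_peak_location(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    tss_window_bp: int = DEFAULT_TSS_WINDOW,
) -> tuple[list[PeakLocationClass], dict[str, float]]:
    """Summit-based location classes with precedence tss_proximal > genic > intergenic.

    Returns the per-peak classes and the category fractions in percent
    (they sum to 100 up to floating point for any non-empty input).
    """
    tss_by_chrom: dict[str, list[int]] = defaultdict(list)
    span_trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for g in genes:
        tss_by_chrom[g.chrom].append(g.tss)
        span_trees[g.chrom].addi(g.interval.start, g.interval.end, g.gene_id)
    for positions in tss_by_chrom.values():
        positions.sort()

    classes: list[PeakLocationClass] = []
    for peak in peaks:
        s = peak.summit_or_midpoint()
        category = "intergenic"
        tss_list = tss_by_chrom.get(peak.chrom, [])
        i = bisect.bisect_left(tss_list, s)
        near_tss = any(
            abs(tss_list[j] - s) <= tss_window_bp
            for j in (i - 1, i)
            if 0 <= j < len(tss_list)
        )
        if near_tss:
            category = "tss_proximal"
        elif span_trees.get(peak.chrom) and span_trees[peak.chrom].overlap(s, s + 1):
            category = "genic"
        classes.append(PeakLocationClass(peak, category))

    n = len(classes)
    fractions = {
        cat: (100.0 * sum(1 for c in classes if c.category == cat) / n if n else float("nan"))
        for cat in LOCATION_CATEGORIES
    }
    return classes, fractions


def replicate_overlap(peak_sets: Mapping[str, Sequence[Peak]]) -> ReplicateOverlapReport:
    """Pairwise peak-set agreement between named replicate sets.

    fraction[A, B] = percent of A's peaks with >= 1 bp overlap into B;
    self-pairs are 100 by construction.  Empty sets yield NaN rows and are
    listed in ``undefined`` rather than being reported as 0.
    """
    if len(peak_sets) < 2:
        raise ValueError("replicate_overlap needs at least two peak sets")
    names = list(peak_sets)
    trees: dict[str, dict[str, IntervalTree]] = {}
    merged: dict[str, list[GenomicInterval]] = {}
    for name, peaks in peak_sets.items():
        t: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for p in peaks:
            t[p.chrom].addi(p.interval.start, p.interval.end)
        trees[name] = t
        merged[name] = merge_intervals(p.interval for p in peaks)

    undefined = {name for name in names if not peak_sets[name]}
    frac = pd.DataFrame(index=names, columns=names, dtype=float)
    jac = pd.DataFrame(index=names, columns=names, dtype=float)
    for a in names:
        for b in names:
            peaks_a = peak_sets[a]
            if not peaks_a:
                frac.at[a, b] = float("nan")
            else:
                hits = sum(
                    1
                    for p in peaks_a
                    if p.chrom in trees[b] and trees[b][p.chrom].overlap(p.interval.start, p.interval.end)
                )
                frac.at[a, b] = 100.0 * hits / len(peaks_a)
            jac.at[a, b] = _bp_jaccard(merged[a], merged[b])
    return ReplicateOverlapReport(names, frac, jac, undefined)


def _bp_jaccard(a: list[GenomicInterval], b: list[GenomicInterval]) -> float:
    inter = 0
    by_chrom_b: dict[str, list[GenomicInterval]] = defaultdict(list)
    for iv in b:
        by_chrom_b[iv.chrom].append(iv)
    for iv in a:
        for jv in by_chrom_b.get(iv.chrom, []):
            inter += max(0, min(iv.end, jv.end) - max(iv.start, jv.start))
    union = sum(iv.length for iv in a) + sum(iv.length for iv in b) - inter
    return inter / union if union else float("nan")


def round_half_up(x: float) -> int:
    """Display rounding for replicate means (6267.67 -> 6268)."""
    return int(math.floor(x + 0.5))


def replicate_summary(
    peak_sets: Mapping[str, Sequence[Peak]],
    genes: Optional[Sequence[GeneModel]] = None,
    window_bp: int = DEFAULT_GENE_WINDOW,
) -> pd.DataFrame:
    """Per-replicate peak counts (and assigned-gene set sizes) with their mean.

    The mean row is rounded half-up for display, reproducing the convention
    of quoting e.g. 6,268 for replicate counts (6902, 4903, 6998).
    """
    rows = {}
    for name, peaks in peak_sets.items():
        row = {"n_peaks": len(peaks)}
        if genes is not None:
            assigned = {a.gene_id for a in assign_peaks_to_genes(peaks, genes, window_bp)}
            row["n_genes"] = len(assigned)
        rows[name] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.loc["mean"] = [round_half_up(df[c].mean()) for c in df.columns]
    return df.astype(int)


def extract_summit_windows(
    peaks: Sequence[Peak],
    genome: GenomeSequence,
    width_bp: int = DEFAULT_SUMMIT_SEQ_WIDTH,
) -> tuple[dict[str, str], int]:
    """Fixed-width sequences centered on each peak summit, FASTA-ready.

    For summit s the window is [s - width/2, s + width/2).  Windows that
    would cross a chromosome boundary are dropped; the drop count is
    returned alongside the name -> sequence mapping.
    """
    if width_bp % 2 != 0 or width_bp <= 0:
        raise ValueError("width_bp must be a positive even number")
    half = width_bp // 2
    windows: dict[str, str] = {}
    dropped = 0
    for i, peak in enumerate(peaks):
        s = peak.summit_or_midpoint()
        lo, hi = s - half, s + half
        if lo < 0 or hi > len(genome[peak.chrom]):
            dropped += 1
            continue
        name = f"{peak.chrom}:{lo}-{hi}|{peak.name or f'peak_{i + 1}'}"
        windows[name] = genome.slice(peak.chrom, lo, hi)
    if dropped:
        logger.info("extract_summit_windows: dropped %d window(s) crossing chromosome boundaries", dropped)
    return windows, dropped
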