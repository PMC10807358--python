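"""Four-criteria nomination of cell type-specific direct TF targets.

A gene is called a putative cell type-specific direct target when, per
antibody:

1. it is novel — absent from a supplied known-target exclusion list
   (default: the six established direct Pnt targets pros, hh, stg, sv,
   tll, edl);
2. a ChIP peak (pooled over replicates; a minimum replicate-support knob
   is available) lies within 2 kb of the gene span, edge to edge;
3. that ChIP peak overlaps an ATAC accessibility peak by >= 1 bp;
4. the gene's cluster-level expression is cell type-specific — tau >= 0.8
   with the top cluster in the configured target-cluster set (default
   emulating photoreceptor R1-7 and cone clusters) and expression above
   threshold somewhere.

Ets-core counts around the supporting summits are annotated descriptively
but never gate a call.  tau is the standard tissue-specificity index
``sum_i (1 - x_i / x_max) / (N - 1)`` over the N cluster means: 0 for
uniform expression, 1 for single-cluster expression.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotate import DEFAULT_GENE_WINDOW, assign_peaks_to_genes
from .expression import DEFAULT_MIN_FRAC, DEFAULT_MIN_MEAN, ExpressionSummary
from .intervals import GeneModel, GenomicInterval, Peak, validate_chromosome_names
from .io import GenomeSequence
from .motifs import DEFAULT_SUMMIT_WINDOW, count_sites_near_summits

logger = logging.getLogger(__name__)

DEFAULT_TAU_MIN = 0.8
KNOWN_PNT_TARGETS = frozenset({"pros", "hh", "stg", "sv", "tll", "edl"})
DEFAULT_TARGET_CLUSTERS = frozenset({"R1-7", "cone"})

CRITERIA = ("c1_novel", "c2_chip_2kb", "c3_atac_overlap", "c4_specific")


# ---------------------------------------------------------------------------
# specificity (tau)

@dataclass(frozen=True)
class SpecificityScore:
    gene_id: str
    tau: Optional[float]  # None when the gene is silent everywhere
    top_cluster: Optional[str]
    expressing_clusters: frozenset[str]
    specific: bool
    in_target_clusters: bool


def tau_index(values: Sequence[float]) -> Optional[float]:
    """Tissue-specificity index over cluster means; None when all-zero."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("tau requires a vector of >= 2 cluster means")
    if (x < 0).any():
        raise ValueError("tau requires non-negative expression values")
    xmax = x.max()
    if xmax == 0:
        return None
    return float(np.sum(1.0 - x / xmax) / (x.size - 1))


def specificity(
    expr: ExpressionSummary,
    tau_min: float = DEFAULT_TAU_MIN,
    min_mean: float = DEFAULT_MIN_MEAN,
    min_frac: float = DEFAULT_MIN_FRAC,
    target_clusters: Optional[Iterable[str]] = DEFAULT_TARGET_CLUSTERS,
) -> list[SpecificityScore]:
    """Score every gene; specific iff tau >= tau_min and expressed somewhere.

    ``target_clusters=None`` disables the cluster restriction (every top
    cluster counts as in-target).
    """
    if len(expr.clusters) < 2:
        raise ValueError("specificity requires >= 2 clusters (tau undefined otherwise)")
    targets = None if target_clusters is None else set(target_clusters)
    scores: list[SpecificityScore] = []
    for gene in expr.genes:
        means = expr.mean.loc[gene]
        tau = tau_index(means.to_numpy())
        expressed = frozenset(expr.expressed_clusters(gene, min_mean, min_frac))
        if tau is None:
            scores.append(SpecificityScore(gene, None, None, expressed, False, False))
            continue
        top_cluster = means.idxmax()
        specific = tau >= tau_min and bool(expressed)
        in_target = top_cluster in targets if targets is not None else True
        scores.append(SpecificityScore(gene, tau, top_cluster, expressed, specific, in_target))
    return scores


# ---------------------------------------------------------------------------
# replicate pooling and ATAC linkage

@dataclass(frozen=True)
class MergedPeak:
    """Union of overlapping ChIP peaks across replicates, with its supporters."""

    interval: GenomicInterval
    members: tuple[Peak, ...]
    replicates: frozenset[str]

    def as_peak(self) -> Peak:
        """Representative Peak (summit of the best-scoring member) for interval ops."""
        best = max(self.members, key=lambda p: p.score)
        s = best.summit_or_midpoint()
        return Peak(
            interval=self.interval,
            summit_offset=s - self.interval.start,
            score=best.score,
            replicate_id="pooled",
            assay="chip",
            name=best.name,
        )


def pool_replicate_peaks(
    replicate_sets: Mapping[str, Sequence[Peak]],
    min_replicates: int = 1,
) -> list[MergedPeak]:
    """Merge overlapping peaks across replicates; keep merged regions with
    support from at least ``min_replicates`` distinct replicates."""
    by_chrom: dict[str, list[Peak]] = defaultdict(list)
    for rep_id, peaks in replicate_sets.items():
        for p in peaks:
            rep = p.replicate_id or rep_id
            if p.replicate_id != rep:
                p = Peak(p.interval, p.summit_offset, p.score, rep, p.assay, p.cluster, p.name)
            by_chrom[p.chrom].append(p)
    merged: list[MergedPeak] = []
    for chrom in sorted(by_chrom):
        peaks = sorted(by_chrom[chrom], key=lambda p: (p.interval.start, p.interval.end))
        group: list[Peak] = [peaks[0]]
        cur_end = peaks[0].interval.end
        for p in peaks[1:]:
            if p.interval.start < cur_end:
                group.append(p)
                cur_end = max(cur_end, p.interval.end)
            else:
                merged.append(_finish_group(chrom, group))
                group = [p]
                cur_end = p.interval.end
        merged.append(_finish_group(chrom, group))
    return [m for m in merged if len(m.replicates) >= min_replicates]


def _finish_group(chrom: str, group: list[Peak]) -> MergedPeak:
    start = min(p.interval.start for p in group)
    end = max(p.interval.end for p in group)
    return MergedPeak(
        GenomicInterval(chrom, start, end),
        tuple(group),
        frozenset(p.replicate_id for p in group),
    )


def pooled_atac(atac_peak_sets: Mapping[str, Sequence[Peak]]) -> list[Peak]:
    """Union (concatenation) of the per-cluster ATAC peak sets."""
    pooled: list[Peak] = []
    for cluster, peaks in atac_peak_sets.items():
        for p in peaks:
            if p.cluster != cluster:
                p = Peak(p.interval, p.summit_offset, p.score, p.replicate_id, p.assay, cluster, p.name)
            pooled.append(p)
    return pooled


def chip_atac_linked_peaks(
    chip_peaks: Sequence[Peak],
    atac_peak_sets: Mapping[str, Sequence[Peak]],
) -> list[tuple[bool, frozenset[str]]]:
    """Per ChIP peak: does any ATAC peak overlap it, and from which clusters."""
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for cluster, peaks in atac_peak_sets.items():
        for p in peaks:
            trees[p.chrom].addi(p.interval.start, p.interval.end, cluster)
    out: list[tuple[bool, frozenset[str]]] = []
    for peak in chip_peaks:
        tree = trees.get(peak.chrom)
        hits = tree.overlap(peak.interval.start, peak.interval.end) if tree else set()
        clusters = frozenset(h.data for h in hits)
        out.append((bool(hits), clusters))
    return out


# ---------------------------------------------------------------------------
# target calling

@dataclass(frozen=True)
class TargetCall:
    gene_id: str
    supporting_chip_peaks: tuple[MergedPeak, ...]
    atac_overlapping: bool
    atac_clusters: frozenset[str]
    specific: bool
    in_target_clusters: bool
    tau: Optional[float]
    top_cluster: Optional[str]
    n_ets_sites_max: Optional[int]
    passed_criteria: frozenset[str]
    verdict: bool


@dataclass
class AntibodyTargets:
    antibody: str
    calls: list[TargetCall]

    @property
    def called_genes(self) -> list[str]:
        return sorted(c.gene_id for c in self.calls if c.verdict)


def call_targets(
    chip_peak_sets: Mapping[str, Mapping[str, Sequence[Peak]]],
    atac_peak_sets: Mapping[str, Sequence[Peak]],
    genes: Sequence[GeneModel],
    expr: ExpressionSummary,
    genome: Optional[GenomeSequence] = None,
    known_targets: Iterable[str] = KNOWN_PNT_TARGETS,
    window_bp: int = DEFAULT_GENE_WINDOW,
    min_replicates_c2: int = 1,
    tau_min: float = DEFAULT_TAU_MIN,
    min_mean: float = DEFAULT_MIN_MEAN,
    min_frac: float = DEFAULT_MIN_FRAC,
    target_clusters: Optional[Iterable[str]] = DEFAULT_TARGET_CLUSTERS,
    ets_window_bp: int = DEFAULT_SUMMIT_WINDOW,
) -> dict[str, AntibodyTargets]:
    """Apply the four criteria per antibody.

    ``chip_peak_sets`` maps antibody -> replicate id -> peaks.  A TargetCall
    is produced for every gene with at least one pooled ChIP peak within the
    window; its verdict is True iff all four criteria pass.  When ``genome``
    is supplied, the maximum Ets-core count within ``ets_window_bp`` of a
    supporting summit is annotated (it never affects the verdict).
    """
    known = {k for k in known_targets}
    gene_by_id = {g.gene_id: g for g in genes}
    if len(gene_by_id) != len(genes):
        raise ValueError("duplicate gene ids in the gene table")

    if genome is not None:
        referenced = {p.chrom for reps in chip_peak_sets.values() for ps in reps.values() for p in ps}
        referenced |= {p.chrom for ps in atac_peak_sets.values() for p in ps}
        referenced |= {g.chrom for g in genes}
        validate_chromosome_names(referenced, genome.lengths, "peak/gene input")

    spec_by_gene = {
        s.gene_id: s
        for s in specificity(expr, tau_min, min_mean, min_frac, target_clusters)
    }

    results: dict[str, AntibodyTargets] = {}
    for antibody, replicate_sets in chip_peak_sets.items():
        merged = pool_replicate_peaks(replicate_sets, min_replicates_c2)
        rep_peaks = [m.as_peak() for m in merged]
        assignments = assign_peaks_to_genes(rep_peaks, genes, window_bp)
        linked = chip_atac_linked_peaks(rep_peaks, atac_peak_sets)
        peak_index = {id(p): i for i, p in enumerate(rep_peaks)}

        per_gene: dict[str, list[int]] = defaultdict(list)
        for a in assignments:
            per_gene[a.gene_id].append(peak_index[id(a.peak)])

        ets_max: dict[int, int] = {}
        if genome is not None:
            member_peaks = [(i, p) for i, m in enumerate(merged) for p in m.members]
            counts = count_sites_near_summits([p for _, p in member_peaks], genome, ets_window_bp)
            for (i, _), c in zip(member_peaks, counts):
                ets_max[i] = max(ets_max.get(i, 0), c.n_sites)

        calls: list[TargetCall] = []
        for gene_id in sorted(per_gene):
            idxs = per_gene[gene_id]
            gene = gene_by_id[gene_id]
            novel = gene_id not in known and gene.name not in known
            atac_hit = any(linked[i][0] for i in idxs)
            atac_clusters = frozenset().union(*(linked[i][1] for i in idxs))
            s = spec_by_gene.get(gene_id)
            specific = s.specific if s else False
            in_target = s.in_target_clusters if s else False
            passed = set()
            if novel:
                passed.add("c1_novel")
            passed.add("c2_chip_2kb")
            if atac_hit:
                passed.add("c3_atac_overlap")
            if specific and in_target:
                passed.add("c4_specific")
            n_ets = max((ets_max.get(i, 0) for i in idxs), default=0) if genome is not None else None
            calls.append(
                TargetCall(
                    gene_id=gene_id,
                    supporting_chip_peaks=tuple(merged[i] for i in idxs),
                    atac_overlapping=atac_hit,
                    atac_clusters=atac_clusters,
                    specific=specific,
                    in_target_clusters=in_target,
                    tau=s.tau if s else None,
                    top_cluster=s.top_cluster if s else None,
                    n_ets_sites_max=n_ets,
                    passed_criteria=frozenset(passed),
                    verdict=set(CRITERIA) <= passed,
                )
            )
        results[antibody] = AntibodyTargets(antibody, calls)
    return results


# ---------------------------------------------------------------------------
# gene-list comparison

@dataclass(frozen=True)
class GeneListComparison:
    n_a: int
    n_b: int
    n_intersection: int
    n_union: int
    intersection: frozenset[str]
    union: frozenset[str]
    only_a: frozenset[str]
    only_b: frozenset[str]


def compare_gene_lists(list_a: Iterable[str], list_b: Iterable[str]) -> GeneListComparison:
    """Set algebra on two gene lists; inclusion-exclusion verified internally."""
    a, b = set(list_a), set(list_b)
    inter, union = a & b, a | b
    assert len(union) == len(a) + len(b) - len(inter)
    return GeneListComparison(
        len(a), len(b), len(inter), len(union),
        frozenset(inter), frozenset(union), frozenset(a - b), frozenset(b - a),
    )


def write_target_calls(calls: Sequence[TargetCall], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "#gene_id\tverdict\tc1_novel\tc2_chip_2kb\tc3_atac_overlap\tc4_specific\t"
            "tau\ttop_cluster\tn_ets_sites_max\tatac_clusters\tsupporting_peaks\n"
        )
        for c in calls:
            flags = "\t".join(str(int(crit in c.passed_criteria)) for crit in CRITERIA)
            tau = "NA" if c.tau is None else f"{c.tau:.4f}"
            n_ets = "NA" if c.n_ets_sites_max is None else str(c.n_ets_sites_max)
            peaks = ",".join(str(m.interval) for m in c.supporting_chip_peaks)
            clusters = ",".join(sorted(c.atac_clusters)) or "."
            fh.write(
                f"{c.gene_id}\t{int(c.verdict)}\t{flags}\t{tau}\t{c.top_cluster or 'NA'}\t"
                f"{n_ets}\t{clusters}\t{peaks}\n"
            )
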