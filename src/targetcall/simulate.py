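"""Synthetic genomes, peaks and expression summaries with planted ground truth.

The generator emulates the statistical structure the target-calling
pipeline consumes: a uniform-composition genome carrying non-overlapping
gene models; for each planted target gene a summit-centered ChIP peak
within 2 kb of the gene whose sequence is overwritten with a controlled
number of Ets cores near the summit (the summit window is purged of
accidental cores so the planted count is exact); five ChIP replicates that
each retain each true peak independently with probability
``replicate_sensitivity``; cluster-restricted ATAC peaks overlapping the
target peaks; and a gene x cluster expression summary in which target
genes are expressed only in the target clusters.  Background genes with
peaks are broadly expressed (low tau), so they exercise criterion 4
without ever being callable.

Draws that depend on ``replicate_sensitivity`` come from fixed-shape
arrays taken at a fixed point in the random stream, so two simulations
differing only in sensitivity share every other draw and the retained-peak
sets are nested (recall is monotone per seed, not only in expectation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .cofactors import MotifTable, read_motif_tables, write_motif_tables
from .expression import ExpressionSummary
from .intervals import GeneModel, GenomicInterval, Peak
from .io import (
    GenomeSequence,
    read_bed,
    read_fasta,
    read_gene_table,
    read_narrowpeak,
    write_bed,
    write_fasta,
    write_gene_table,
    write_narrowpeak,
)
from .motifs import ALL_CORES, CORE_LEN, scan_ets_sites

logger = logging.getLogger(__name__)

BASES = np.frombuffer(b"ACGT", dtype="S1")
CORES_BYTES = tuple(c.encode() for c in ALL_CORES)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset; every field has a tested default."""

    seed: int = 0
    n_chromosomes: int = 2
    chromosome_length: int = 500_000
    n_genes: int = 60
    gene_length_range: tuple[int, int] = (2_000, 6_000)
    cluster_labels: tuple[str, ...] = ("progenitor", "MF", "R8", "R1-7", "cone", "pigment")
    target_clusters: tuple[str, ...] = ("R1-7", "cone")
    n_target_genes: int = 20
    n_background_genes_with_peaks: int = 10
    n_replicates: int = 5
    replicate_sensitivity: float = 1.0
    peak_width_range: tuple[int, int] = (200, 500)
    n_planted_ets_sites: int = 3
    ets_site_window: int = 200
    peak_gene_max_gap: int = 2_000
    atac_match_prob: float = 1.0
    background_peak_rate: float = 5.0  # peaks per Mb per replicate
    # expression design
    expr_on_mean_range: tuple[float, float] = (1.5, 3.0)
    expr_on_frac_range: tuple[float, float] = (0.5, 0.8)
    expr_broad_mean_range: tuple[float, float] = (0.8, 1.2)
    # cofactor motif tables
    bait_gene: str = "pnt"
    consensus_motifs: tuple[tuple[str, tuple[str, ...]], ...] = (
        ("Ets", ("pnt", "aop")),
        ("M_crol", ("crol",)),
        ("M_ttk", ("ttk",)),
        ("M_aef1", ("aef1",)),
        ("M_klu", ("klu",)),
        ("M_beaf32", ("BEAF-32",)),
        ("M_med", ("Med",)),
        ("M_mad", ("Mad",)),
        ("M_cg15812", ("CG15812",)),
        ("M_prd", ("prd",)),
    )
    silent_cofactors: tuple[str, ...] = ("prd",)
    noncoexpressed_cofactors: tuple[str, ...] = ("CG15812",)
    n_decoy_motifs: int = 15
    motif_table_min_support: int = 4

    def __post_init__(self) -> None:
        for p in (self.replicate_sensitivity, self.atac_match_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.n_target_genes + self.n_background_genes_with_peaks > self.n_genes:
            raise ValueError("more planted genes than genes")
        if not set(self.target_clusters) <= set(self.cluster_labels):
            raise ValueError("target_clusters must be a subset of cluster_labels")
        if self.n_planted_ets_sites < 0 or self.n_replicates < 1:
            raise ValueError("invalid counts in simulation config")

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_labels)


@dataclass
class GroundTruth:
    target_gene_ids: set[str]
    background_gene_ids: set[str]
    table: pd.DataFrame  # gene_id, chrom, peak_start, peak_end, summit, n_sites, clusters, is_target
    retained_cofactors: set[str]


@dataclass
class SimulatedData:
    config: SimulationConfig
    genome: GenomeSequence
    genes: list[GeneModel]
    chip: dict[str, list[Peak]]  # replicate id -> peaks
    atac: dict[str, list[Peak]]  # cluster -> peaks
    expression: ExpressionSummary
    motif_tables: list[MotifTable]
    truth: GroundTruth


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def simulate_genome(config: SimulationConfig) -> GenomeSequence:
    """I.i.d. uniform A/C/G/T background, one chromosome per config slot."""
    rng = _rng(config, 0)
    seqs = {}
    for c in range(config.n_chromosomes):
        draws = rng.integers(0, 4, size=config.chromosome_length)
        seqs[f"chr{c + 1}"] = BASES[draws].tobytes().decode()
    return GenomeSequence(seqs)


def _slot_margin(config: SimulationConfig) -> int:
    return (
        config.peak_gene_max_gap
        + config.peak_width_range[1]
        + config.ets_site_window
        + 50
    )


def simulate_genes(config: SimulationConfig, genome: GenomeSequence) -> list[GeneModel]:
    """Place genes on an even grid so no gene sits within the peak window of another."""
    rng = _rng(config, 1)
    chroms = sorted(genome.lengths)
    per_chrom = [config.n_genes // config.n_chromosomes] * config.n_chromosomes
    for i in range(config.n_genes % config.n_chromosomes):
        per_chrom[i] += 1
    margin = _slot_margin(config)
    genes: list[GeneModel] = []
    idx = 0
    for chrom, n in zip(chroms, per_chrom):
        if n == 0:
            continue
        slot = genome.lengths[chrom] // n
        if slot < config.gene_length_range[1] + 2 * margin:
            raise ValueError(
                f"infeasible placement: slot {slot} bp on {chrom} cannot hold a gene of "
                f"{config.gene_length_range[1]} bp plus {margin} bp margins"
            )
        for j in range(n):
            idx += 1
            length = int(rng.integers(*config.gene_length_range, endpoint=True))
            start = j * slot + margin
            strand = "+" if rng.random() < 0.5 else "-"
            gid = f"g{idx:03d}"
            genes.append(
                GeneModel(gid, gid, GenomicInterval(chrom, start, start + length, strand), strand)
            )
    return genes


def _purge_window(
    buf: bytearray, lo: int, hi: int, planted_starts: set[int], planted_mask: set[int],
    rng: np.random.Generator,
) -> None:
    """Remove every accidental Ets core starting in [lo, hi] without touching planted bases."""
    for _ in range(500):
        offender = -1
        for p in range(max(0, lo), min(len(buf) - CORE_LEN, hi) + 1):
            if bytes(buf[p : p + CORE_LEN]) in CORES_BYTES and p not in planted_starts:
                offender = p
                break
        if offender < 0:
            return
        free = [i for i in range(offender, offender + CORE_LEN) if i not in planted_mask]
        pos = free[int(rng.integers(len(free)))]
        buf[pos] = BASES[int(rng.integers(4))][0]
    raise RuntimeError("purge of accidental Ets cores did not converge")


def plant_targets(
    config: SimulationConfig, genome: GenomeSequence, genes: Sequence[GeneModel]
) -> SimulatedData:
    """Plant target peaks, replicate them, and derive ATAC/expression/motif data."""
    rng = _rng(config, 2)
    buffers = {c: bytearray(s, "ascii") for c, s in genome.sequences.items()}

    n_planted = config.n_target_genes + config.n_background_genes_with_peaks
    chosen = rng.choice(len(genes), size=n_planted, replace=False)
    target_genes = [genes[i] for i in chosen[: config.n_target_genes]]
    bg_genes = [genes[i] for i in chosen[config.n_target_genes :]]

    true_peaks: list[dict] = []  # one per planted gene
    for gene, is_target in [(g, True) for g in target_genes] + [(g, False) for g in bg_genes]:
        w = int(rng.integers(*config.peak_width_range, endpoint=True))
        if rng.random() < 0.5:  # overlap the gene's 5' span edge
            start = gene.interval.start - w // 2
        else:  # fully upstream, gap in [1, max_gap]
            gap = int(rng.integers(1, config.peak_gene_max_gap, endpoint=True))
            start = gene.interval.start - gap - w
        end = start + w
        summit = start + w // 2
        chrom_len = genome.lengths[gene.chrom]
        if start < config.ets_site_window + CORE_LEN or end > chrom_len - config.ets_site_window - CORE_LEN:
            raise ValueError(
                f"infeasible placement: peak for {gene.gene_id} too close to the edge of {gene.chrom}"
            )
        n_sites = 0
        if is_target and config.n_planted_ets_sites > 0:
            buf = buffers[gene.chrom]
            grid = np.arange(summit - config.ets_site_window, summit + config.ets_site_window - CORE_LEN + 2, CORE_LEN + 1)
            positions = sorted(int(p) for p in rng.choice(grid, size=config.n_planted_ets_sites, replace=False))
            planted_starts, planted_mask = set(), set()
            for pos in positions:
                core = CORES_BYTES[int(rng.integers(len(CORES_BYTES)))]
                buf[pos : pos + CORE_LEN] = core
                planted_starts.add(pos)
                planted_mask.update(range(pos, pos + CORE_LEN))
            _purge_window(
                buf,
                summit - config.ets_site_window,
                summit + config.ets_site_window,
                planted_starts,
                planted_mask,
                rng,
            )
            n_sites = config.n_planted_ets_sites
        true_peaks.append(
            dict(gene=gene, start=start, end=end, summit=summit, is_target=is_target, n_sites=n_sites)
        )

    # --- fixed-shape stochastic draws (sensitivity-coupled; see module docstring)
    n_true = len(true_peaks)
    R = config.n_replicates
    retain_u = rng.random((R, n_true))
    jitter = rng.integers(0, 26, size=(R, n_true, 2))
    atac_u = rng.random(n_true)
    atac_jitter = rng.integers(0, 51, size=(n_true, 2))

    chip: dict[str, list[Peak]] = {}
    for r in range(R):
        rep_id = f"rep{r + 1}"
        peaks: list[Peak] = []
        for i, tp in enumerate(true_peaks):
            if retain_u[r, i] >= config.replicate_sensitivity:
                continue
            d1, d2 = int(jitter[r, i, 0]), int(jitter[r, i, 1])
            start, end = tp["start"] - d1, tp["end"] + d2
            peaks.append(
                Peak(
                    interval=GenomicInterval(tp["gene"].chrom, start, end),
                    summit_offset=tp["summit"] - start,
                    score=10.0,
                    replicate_id=rep_id,
                    assay="chip",
                    name=f"{tp['gene'].gene_id}_{rep_id}",
                )
            )
        chip[rep_id] = peaks

    # background ChIP peaks, kept clear of planted configurations
    exclusion = [
        (tp["gene"].chrom, tp["start"] - 1_000, tp["end"] + 1_000) for tp in true_peaks
    ]
    genome_mb = config.n_chromosomes * config.chromosome_length / 1e6
    chrom_names = sorted(genome.lengths)
    for r in range(R):
        n_bg = int(rng.poisson(config.background_peak_rate * genome_mb))
        placed = 0
        attempts = 0
        while placed < n_bg and attempts < 50 * max(1, n_bg):
            attempts += 1
            chrom = chrom_names[int(rng.integers(len(chrom_names)))]
            w = int(rng.integers(*config.peak_width_range, endpoint=True))
            start = int(rng.integers(0, genome.lengths[chrom] - w))
            if any(c == chrom and start < e and start + w > s for c, s, e in exclusion):
                continue
            placed += 1
            chip[f"rep{r + 1}"].append(
                Peak(
                    interval=GenomicInterval(chrom, start, start + w),
                    summit_offset=w // 2,
                    score=5.0,
                    replicate_id=f"rep{r + 1}",
                    assay="chip",
                    name=f"bg_rep{r + 1}_{placed}",
                )
            )
    for peaks in chip.values():
        peaks.sort(key=lambda p: (p.chrom, p.interval.start, p.interval.end))

    # --- ATAC peaks: matched accessibility for planted peaks, plus background
    atac: dict[str, list[Peak]] = {c: [] for c in config.cluster_labels}
    matched_clusters: list[tuple[str, ...]] = []
    for i, tp in enumerate(true_peaks):
        if atac_u[i] < config.atac_match_prob:
            clusters = config.target_clusters if tp["is_target"] else config.cluster_labels
            d1, d2 = int(atac_jitter[i, 0]), int(atac_jitter[i, 1])
            iv = GenomicInterval(tp["gene"].chrom, max(0, tp["start"] - d1), tp["end"] + d2)
            for cluster in clusters:
                atac[cluster].append(
                    Peak(interval=iv, assay="atac", cluster=cluster, name=f"atac_{tp['gene'].gene_id}")
                )
            matched_clusters.append(tuple(clusters))
        else:
            matched_clusters.append(())
    for cluster in config.cluster_labels:
        n_bg = int(rng.poisson(config.background_peak_rate * genome_mb))
        for k in range(n_bg):
            chrom = chrom_names[int(rng.integers(len(chrom_names)))]
            w = int(rng.integers(*config.peak_width_range, endpoint=True))
            start = int(rng.integers(0, genome.lengths[chrom] - w))
            atac[cluster].append(
                Peak(
                    interval=GenomicInterval(chrom, start, start + w),
                    assay="atac",
                    cluster=cluster,
                    name=f"atac_bg_{cluster}_{k + 1}",
                )
            )
        atac[cluster].sort(key=lambda p: (p.chrom, p.interval.start, p.interval.end))

    expression = _simulate_expression(config, genes, target_genes, bg_genes, rng)
    motif_tables = _simulate_motif_tables(config, rng)

    truth_rows = []
    for tp, clusters in zip(true_peaks, matched_clusters):
        truth_rows.append(
            (
                tp["gene"].gene_id,
                tp["gene"].chrom,
                tp["start"],
                tp["end"],
                tp["summit"],
                tp["n_sites"],
                ",".join(clusters) or ".",
                int(tp["is_target"]),
            )
        )
    truth = GroundTruth(
        target_gene_ids={g.gene_id for g in target_genes},
        background_gene_ids={g.gene_id for g in bg_genes},
        table=pd.DataFrame(
            truth_rows,
            columns=["gene_id", "chrom", "peak_start", "peak_end", "summit", "n_sites", "clusters", "is_target"],
        ),
        retained_cofactors=_expected_retained(config),
    )
    final_genome = GenomeSequence({c: buf.decode() for c, buf in buffers.items()})
    return SimulatedData(config, final_genome, list(genes), chip, atac, expression, motif_tables, truth)


def _expected_retained(config: SimulationConfig) -> set[str]:
    factors: set[str] = set()
    for _, fs in config.consensus_motifs:
        factors.update(fs)
    return factors - set(config.silent_cofactors) - set(config.noncoexpressed_cofactors)


def _simulate_expression(
    config: SimulationConfig,
    genes: Sequence[GeneModel],
    target_genes: Sequence[GeneModel],
    bg_genes: Sequence[GeneModel],
    rng: np.random.Generator,
) -> ExpressionSummary:
    clusters = list(config.cluster_labels)
    target_ids = {g.gene_id for g in target_genes}
    bg_ids = {g.gene_id for g in bg_genes}

    cofactor_genes: list[str] = []
    for _, fs in config.consensus_motifs:
        for f in fs:
            if f not in cofactor_genes:
                cofactor_genes.append(f)
    if config.bait_gene not in cofactor_genes:
        cofactor_genes.insert(0, config.bait_gene)

    index = [g.gene_id for g in genes] + cofactor_genes
    mean = pd.DataFrame(0.0, index=index, columns=clusters)
    frac = pd.DataFrame(0.0, index=index, columns=clusters)

    lo_m, hi_m = config.expr_on_mean_range
    lo_f, hi_f = config.expr_on_frac_range
    for g in genes:
        if g.gene_id in target_ids:
            for c in config.target_clusters:
                mean.at[g.gene_id, c] = rng.uniform(lo_m, hi_m)
                frac.at[g.gene_id, c] = rng.uniform(lo_f, hi_f)
        elif g.gene_id in bg_ids:
            lo_b, hi_b = config.expr_broad_mean_range
            for c in clusters:
                mean.at[g.gene_id, c] = rng.uniform(lo_b, hi_b)
                frac.at[g.gene_id, c] = rng.uniform(0.3, 0.6)
        # all other genes stay silent

    # bait expressed everywhere except the last cluster; co-expressed cofactors
    # broadly expressed; silent cofactors stay zero; non-co-expressed ones are
    # confined to that last, bait-free cluster.
    bait_off = clusters[-1]
    for c in clusters:
        if c != bait_off:
            mean.at[config.bait_gene, c] = rng.uniform(lo_m, hi_m)
            frac.at[config.bait_gene, c] = rng.uniform(lo_f, hi_f)
    for f in cofactor_genes:
        if f == config.bait_gene or f in config.silent_cofactors:
            continue
        if f in config.noncoexpressed_cofactors:
            mean.at[f, bait_off] = rng.uniform(lo_m, hi_m)
            frac.at[f, bait_off] = rng.uniform(lo_f, hi_f)
        else:
            for c in clusters[:-1]:
                mean.at[f, c] = rng.uniform(0.5, 2.0)
                frac.at[f, c] = rng.uniform(0.2, 0.6)
    return ExpressionSummary(mean, frac)


def _simulate_motif_tables(config: SimulationConfig, rng: np.random.Generator) -> list[MotifTable]:
    R = config.n_replicates
    decoys = [(f"dec{i + 1:02d}", (f"decTF{i + 1:02d}",)) for i in range(config.n_decoy_motifs)]

    presence: dict[str, list[int]] = {}
    for motif_id, _ in config.consensus_motifs:
        support = int(rng.integers(config.motif_table_min_support, R, endpoint=True))
        presence[motif_id] = sorted(rng.choice(R, size=support, replace=False).tolist())
    for motif_id, _ in decoys:
        support = int(rng.integers(1, config.motif_table_min_support - 1, endpoint=True))
        presence[motif_id] = sorted(rng.choice(R, size=support, replace=False).tolist())

    factor_of = dict(config.consensus_motifs) | dict(decoys)
    tables: list[MotifTable] = []
    for r in range(R):
        consensus_here = [m for m, _ in config.consensus_motifs if r in presence[m]]
        decoys_here = [m for m, _ in decoys if r in presence[m]]
        consensus_here = [consensus_here[i] for i in rng.permutation(len(consensus_here))]
        decoys_here = [decoys_here[i] for i in rng.permutation(len(decoys_here))]
        motifs = consensus_here + decoys_here  # consensus motifs always rank highest
        rows = []
        for rank, motif_id in enumerate(motifs, start=1):
            evalue = 1e-30 * 10 ** (1.2 * (rank - 1)) * float(rng.uniform(1.0, 2.0))
            rows.append((rank, motif_id, tuple(factor_of[motif_id]), evalue))
        df = pd.DataFrame(rows, columns=["rank", "motif_id", "factors", "evalue"])
        df["evalue"] = df["evalue"].cummax()  # keep non-decreasing despite noise
        tables.append(MotifTable(f"rep{r + 1}", df))
    return tables


def simulate(config: SimulationConfig) -> SimulatedData:
    """Full generator: genome, genes, then planting and all derived data."""
    genome = simulate_genome(config)
    genes = simulate_genes(config, genome)
    return plant_targets(config, genome, genes)


# ---------------------------------------------------------------------------
# fixture round-trip

def write_fixture(sim: SimulatedData, dir_path) -> None:
    """Emit the complete fixture in the pipeline's input dialects."""
    d = Path(dir_path)
    d.mkdir(parents=True, exist_ok=True)
    write_fasta(sim.genome.sequences, d / "genome.fa")
    write_gene_table(sim.genes, d / "genes.tsv")
    for rep_id, peaks in sim.chip.items():
        write_narrowpeak(peaks, d / f"chip_{rep_id}.narrowPeak")
    for cluster, peaks in sim.atac.items():
        write_bed(peaks, d / f"atac_{cluster}.bed", with_cluster=True)
    sim.expression.write_tsv(d / "expression.tsv")
    write_motif_tables(sim.motif_tables, d / "motifs.tsv")
    with open(d / "ground_truth.tsv", "w") as fh:
        fh.write("#gene_id\tchrom\tpeak_start\tpeak_end\tsummit\tn_sites\tclusters\tis_target\n")
        for row in sim.truth.table.itertuples(index=False):
            fh.write("\t".join(str(v) for v in row) + "\n")


@dataclass
class Fixture:
    genome: GenomeSequence
    genes: list[GeneModel]
    chip: dict[str, list[Peak]]
    atac: dict[str, list[Peak]]
    expression: ExpressionSummary
    motif_tables: list[MotifTable]
    truth_table: pd.DataFrame


def read_fixture(dir_path) -> Fixture:
    d = Path(dir_path)
    genome = read_fasta(d / "genome.fa")
    genes = read_gene_table(d / "genes.tsv")
    chip = {}
    for path in sorted(d.glob("chip_*.narrowPeak")):
        rep_id = path.stem.removeprefix("chip_")
        chip[rep_id] = read_narrowpeak(path, replicate_id=rep_id)
    atac: dict[str, list[Peak]] = {}
    for path in sorted(d.glob("atac_*.bed")):
        for p in read_bed(path, assay="atac"):
            atac.setdefault(p.cluster, []).append(p)
    expression = ExpressionSummary.read_tsv(d / "expression.tsv")
    motif_tables = read_motif_tables(d / "motifs.tsv")
    truth = pd.read_csv(
        d / "ground_truth.tsv",
        sep="\t",
        names=["gene_id", "chrom", "peak_start", "peak_end", "summit", "n_sites", "clusters", "is_target"],
        skiprows=1,
    )
    return Fixture(genome, genes, chip, atac, expression, motif_tables, truth)


# ---------------------------------------------------------------------------
# parameter-recovery evaluation

def recover_targets(sim: SimulatedData, **call_kwargs):
    """Run the full target-calling pipeline on a simulated dataset."""
    from .targets import call_targets

    kwargs = dict(
        genome=sim.genome,
        target_clusters=sim.config.target_clusters,
        window_bp=sim.config.peak_gene_max_gap,
        ets_window_bp=sim.config.ets_site_window,
    )
    kwargs.update(call_kwargs)
    return call_targets(
        {"chip": sim.chip}, sim.atac, sim.genes, sim.expression, **kwargs
    )["chip"]


def precision_recall(called: Sequence[str], truth_ids: set[str]) -> tuple[float, float]:
    called_set = set(called)
    tp = len(called_set & truth_ids)
    precision = tp / len(called_set) if called_set else float("nan")
    recall = tp / len(truth_ids) if truth_ids else float("nan")
    return precision, recall


def recovery_experiment(
    base_config: SimulationConfig,
    sensitivities: Sequence[float],
    seeds: Sequence[int],
) -> pd.DataFrame:
    """Precision/recall of the full pipeline across sensitivity levels and seeds."""
    rows = []
    for seed in seeds:
        for s in sensitivities:
            config = replace(base_config, seed=seed, replicate_sensitivity=s)
            sim = simulate(config)
            result = recover_targets(sim)
            prec, rec = precision_recall(result.called_genes, sim.truth.target_gene_ids)
            rows.append((seed, s, prec, rec))
    return pd.DataFrame(rows, columns=["seed", "sensitivity", "precision", "recall"])
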