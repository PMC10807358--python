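"""Readers and writers for the plain-text genomic formats the pipeline consumes.

Formats: ENCODE narrowPeak (BED6+4) for ChIP peaks, BED3/BED6 (optional
7th column = cell-cluster label) for ATAC peaks, a minimal TSV gene table,
and FASTA for genome sequence.  All coordinates are taken as 0-based
half-open; parse errors name the offending line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from Bio.SeqIO.FastaIO import SimpleFastaParser

from .intervals import GeneModel, GenomicInterval, Peak

logger = logging.getLogger(__name__)

FASTA_WRAP = 60


class ParseError(ValueError):
    """Malformed record in a tabular genomic file."""


def _err(path, lineno: int, msg: str) -> ParseError:
    return ParseError(f"{path}:{lineno}: {msg}")


def _int_field(path, lineno: int, text: str, what: str) -> int:
    try:
        return int(text)
    except ValueError:
        raise _err(path, lineno, f"non-integer {what}: {text!r}") from None


# ---------------------------------------------------------------------------
# narrowPeak / BED

def read_narrowpeak(path, replicate_id: str = "", assay: str = "chip") -> list[Peak]:
    """Read an ENCODE narrowPeak (BED6+4) file.

    Column 10 (summit offset from peak start) maps -1 to an absent summit.
    Column 7 (signalValue) becomes the peak score.
    """
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) != 10:
                raise _err(path, lineno, f"expected 10 tab-separated columns, got {len(fields)}")
            chrom = fields[0]
            start = _int_field(path, lineno, fields[1], "start")
            end = _int_field(path, lineno, fields[2], "end")
            if end <= start:
                raise _err(path, lineno, f"end {end} <= start {start}")
            if start < 0:
                raise _err(path, lineno, f"negative start {start}")
            strand = fields[5] if fields[5] in ("+", "-") else "."
            signal = float(fields[6])
            summit = _int_field(path, lineno, fields[9], "summit offset")
            if summit == -1:
                summit_offset: Optional[int] = None
            elif 0 <= summit < end - start:
                summit_offset = summit
            else:
                raise _err(path, lineno, f"summit offset {summit} outside peak of length {end - start}")
            peaks.append(
                Peak(
                    interval=GenomicInterval(chrom, start, end, strand),
                    summit_offset=summit_offset,
                    score=max(signal, 0.0),
                    replicate_id=replicate_id,
                    assay=assay,
                    name=fields[3],
                )
            )
    return peaks


def write_narrowpeak(peaks: Sequence[Peak], path) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            summit = -1 if p.summit_offset is None else p.summit_offset
            name = p.name or f"peak_{i + 1}"
            fh.write(
                "\t".join(
                    [
                        p.chrom,
                        str(p.interval.start),
                        str(p.interval.end),
                        name,
                        "0",
                        p.interval.strand if p.interval.strand != "." else ".",
                        f"{p.score:g}",
                        "-1",
                        "-1",
                        str(summit),
                    ]
                )
                + "\n"
            )


def read_bed(path, assay: str = "atac", replicate_id: str = "", cluster: Optional[str] = None) -> list[Peak]:
    """Read BED3/BED6 peaks; an optional 7th column is a cell-cluster label.

    An explicit ``cluster`` argument overrides the column.
    """
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) not in (3, 4, 5, 6, 7):
                raise _err(path, lineno, f"expected 3-7 columns, got {len(fields)}")
            chrom = fields[0]
            start = _int_field(path, lineno, fields[1], "start")
            end = _int_field(path, lineno, fields[2], "end")
            if end <= start:
                raise _err(path, lineno, f"end {end} <= start {start}")
            name = fields[3] if len(fields) >= 4 else ""
            strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "."
            col_cluster = fields[6] if len(fields) == 7 else None
            peaks.append(
                Peak(
                    interval=GenomicInterval(chrom, start, end, strand),
                    assay=assay,
                    replicate_id=replicate_id,
                    cluster=cluster if cluster is not None else col_cluster,
                    name=name,
                )
            )
    return peaks


def write_bed(peaks: Sequence[Peak], path, with_cluster: bool = False) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(peaks):
            fields = [
                p.chrom,
                str(p.interval.start),
                str(p.interval.end),
                p.name or f"peak_{i + 1}",
                "0",
                p.interval.strand,
            ]
            if with_cluster:
                fields.append(p.cluster or ".")
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# gene table

def read_gene_table(path) -> list[GeneModel]:
    """Read the minimal gene table: chrom, start, end, gene_id, name, strand (TSV).

    TSS is derived from strand (start on +, end-1 on -).  Duplicate gene ids
    and unknown strand symbols are errors.
    """
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 6:
                raise _err(path, lineno, f"expected 6 columns, got {len(fields)}")
            chrom, start_s, end_s, gene_id, name, strand = fields
            start = _int_field(path, lineno, start_s, "start")
            end = _int_field(path, lineno, end_s, "end")
            if end <= start:
                raise _err(path, lineno, f"end {end} <= start {start}")
            if strand not in ("+", "-"):
                raise _err(path, lineno, f"unknown strand symbol {strand!r}")
            if gene_id in seen:
                raise _err(path, lineno, f"duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            genes.append(
                GeneModel(gene_id, name, GenomicInterval(chrom, start, end, strand), strand)
            )
    return genes


def write_gene_table(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tgene_id\tname\tstrand\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\t{g.interval.start}\t{g.interval.end}\t{g.gene_id}\t{g.name}\t{g.strand}\n"
            )


# ---------------------------------------------------------------------------
# genome FASTA

@dataclass
class GenomeSequence:
    """In-memory genome: chromosome name -> uppercase DNA over {A,C,G,T,N}."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        bad = {
            name: sorted(set(seq) - set("ACGTN"))
            for name, seq in self.sequences.items()
            if set(seq) - set("ACGTN")
        }
        if bad:
            raise ValueError(f"non-ACGTN characters in sequences: {bad}")

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    def slice(self, chrom: str, start: int, end: int, clip: bool = False) -> str:
        """Substring [start, end); with clip=True, silently clip to the chromosome."""
        seq = self.sequences[chrom]
        if clip:
            start, end = max(0, start), min(len(seq), end)
        elif start < 0 or end > len(seq):
            raise ValueError(f"window {chrom}:{start}-{end} outside chromosome of length {len(seq)}")
        return seq[start:end]


def read_fasta(path) -> GenomeSequence:
    """Read FASTA into a GenomeSequence; sequences uppercased, duplicate headers rejected."""
    seqs: dict[str, str] = {}
    with open(path) as fh:
        for title, seq in SimpleFastaParser(fh):
            name = title.split()[0] if title.split() else ""
            if not name:
                raise ParseError(f"{path}: empty FASTA header")
            if name in seqs:
                raise ParseError(f"{path}: duplicate FASTA header {name!r}")
            if not seq:
                raise ParseError(f"{path}: record {name!r} has an empty body")
            seqs[name] = seq.upper()
    return GenomeSequence(seqs)


def write_fasta(seqs: Mapping[str, str], path, wrap: int = FASTA_WRAP) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), wrap):
                fh.write(seq[i : i + wrap] + "\n")
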