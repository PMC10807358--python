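"""Three-stage cofactor-motif filter over replicate motif-discovery tables.

De novo motif discovery on individual ChIP replicates is noisy, so a
candidate cofactor is kept only if it survives, in order:

1. replicate consensus — the factor appears within the top-k motifs of at
   least ``min_replicates`` replicate tables (defaults: top 20, >= 4 of 5);
2. tissue expression — at least one gene mapped to the factor is expressed
   in at least one cell cluster of the expression summary;
3. bait co-expression — the factor's expressing clusters intersect the
   bait transcription factor's expressing clusters.

The verdict records the first failing stage; stages are never evaluated
past the first failure.  Motif-to-factor mapping is an input (a single
motif may map to several factors, e.g. an Ets motif shared by an activator
and a repressor), not something inferred here.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from .expression import DEFAULT_MIN_FRAC, DEFAULT_MIN_MEAN, ExpressionSummary

logger = logging.getLogger(__name__)

DEFAULT_TOP_K = 20
DEFAULT_MIN_REPLICATES = 4

VERDICTS = ("retained", "dropped_consensus", "dropped_expression", "dropped_coexpression")


@dataclass
class MotifTable:
    """Ranked motif-discovery output for one replicate.

    ``table`` columns: rank (1-based), motif_id, factors (tuple of factor
    names the motif is curated to), evalue.  E-values must be non-decreasing
    in rank; violations are warned about and the table re-sorted.
    """

    replicate_id: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"rank", "motif_id", "factors", "evalue"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"motif table {self.replicate_id}: missing columns {required - set(self.table.columns)}")
        if (self.table["evalue"] <= 0).any():
            raise ValueError(f"motif table {self.replicate_id}: E-values must be positive")
        tab = self.table.sort_values("rank", kind="stable").reset_index(drop=True)
        if not tab["evalue"].is_monotonic_increasing:
            logger.warning(
                "motif table %s: E-values not non-decreasing in rank; re-sorting by E-value",
                self.replicate_id,
            )
            tab = tab.sort_values("evalue", kind="stable").reset_index(drop=True)
            tab["rank"] = range(1, len(tab) + 1)
        self.table = tab

    def top_factors(self, top_k: int) -> set[str]:
        """Factor names appearing among the top_k motifs."""
        if top_k > len(self.table):
            logger.info(
                "motif table %s: top_k=%d exceeds table size %d; using whole table",
                self.replicate_id,
                top_k,
                len(self.table),
            )
        head = self.table[self.table["rank"] <= top_k]
        out: set[str] = set()
        for factors in head["factors"]:
            out.update(factors)
        return out


def read_motif_tables(path) -> list[MotifTable]:
    """Read a combined motif TSV: replicate_id, rank, motif_id, factors, evalue.

    The factors column holds comma-separated factor names.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        names=["replicate_id", "rank", "motif_id", "factors", "evalue"],
        skiprows=1,
        dtype={"replicate_id": str, "motif_id": str, "factors": str},
    )
    tables = []
    for rep_id, sub in df.groupby("replicate_id", sort=False):
        sub = sub.copy()
        sub["factors"] = sub["factors"].map(lambda s: tuple(s.split(",")))
        tables.append(MotifTable(rep_id, sub[["rank", "motif_id", "factors", "evalue"]]))
    return tables


def write_motif_tables(tables: Sequence[MotifTable], path) -> None:
    with open(path, "w") as fh:
        fh.write("#replicate_id\trank\tmotif_id\tfactors\tevalue\n")
        for t in tables:
            for row in t.table.itertuples(index=False):
                fh.write(
                    f"{t.replicate_id}\t{row.rank}\t{row.motif_id}\t{','.join(row.factors)}\t{row.evalue:.6g}\n"
                )


@dataclass(frozen=True)
class CofactorCall:
    factor: str
    n_replicates_supporting: int
    expressed: Optional[bool]
    coexpressed_with_bait: Optional[bool]
    verdict: str
    unmapped: bool = False


def factor_support(tables: Sequence[MotifTable], top_k: int = DEFAULT_TOP_K) -> Counter:
    """Number of replicate tables in which each factor appears within the top_k motifs."""
    support: Counter = Counter()
    for t in tables:
        support.update(t.top_factors(top_k))
    return support


def consensus_filter(
    tables: Sequence[MotifTable],
    top_k: int = DEFAULT_TOP_K,
    min_replicates: int = DEFAULT_MIN_REPLICATES,
) -> dict[str, int]:
    """Factors supported by at least ``min_replicates`` tables, with their support."""
    if len(tables) < min_replicates:
        raise ValueError(
            f"need at least min_replicates={min_replicates} tables, got {len(tables)}"
        )
    support = factor_support(tables, top_k)
    return {f: n for f, n in support.items() if n >= min_replicates}


def _mapped_genes(factor: str, factor_gene_map: Optional[Mapping[str, Sequence[str]]]) -> list[str]:
    if factor_gene_map is None:
        return [factor]
    return list(factor_gene_map.get(factor, []))


def is_expressed(
    factor_genes: Sequence[str],
    expr: ExpressionSummary,
    min_mean: float = DEFAULT_MIN_MEAN,
    min_frac: float = DEFAULT_MIN_FRAC,
) -> bool:
    """True iff any mapped gene clears a threshold in at least one cluster.

    A factor with no mapped gene present in the matrix is not expressed by
    contract (the caller flags it as unmapped).
    """
    return any(
        gene in expr and expr.expressed_clusters(gene, min_mean, min_frac)
        for gene in factor_genes
    )


def coexpressed_with_bait(
    factor_genes: Sequence[str],
    bait_gene: str,
    expr: ExpressionSummary,
    min_mean: float = DEFAULT_MIN_MEAN,
    min_frac: float = DEFAULT_MIN_FRAC,
) -> bool:
    """True iff factor and bait expressing-cluster sets intersect."""
    if bait_gene not in expr:
        raise ValueError(f"bait gene {bait_gene!r} absent from the expression summary")
    bait_clusters = expr.expressed_clusters(bait_gene, min_mean, min_frac)
    factor_clusters: set[str] = set()
    for gene in factor_genes:
        if gene in expr:
            factor_clusters |= expr.expressed_clusters(gene, min_mean, min_frac)
    return bool(factor_clusters & bait_clusters)


def call_cofactors(
    tables: Sequence[MotifTable],
    expr: ExpressionSummary,
    bait_gene: str,
    factor_gene_map: Optional[Mapping[str, Sequence[str]]] = None,
    top_k: int = DEFAULT_TOP_K,
    min_replicates: int = DEFAULT_MIN_REPLICATES,
    min_mean: float = DEFAULT_MIN_MEAN,
    min_frac: float = DEFAULT_MIN_FRAC,
) -> list[CofactorCall]:
    """Run the three filter stages over every factor seen in any table's top_k.

    Stage order is observable in the verdicts: a factor failing consensus is
    never evaluated for expression, and one failing expression never for
    co-expression (those fields stay None).
    """
    if bait_gene not in expr:
        raise ValueError(f"bait gene {bait_gene!r} absent from the expression summary")
    support = factor_support(tables, top_k)
    calls: list[CofactorCall] = []
    for factor in sorted(support):
        n = support[factor]
        genes = _mapped_genes(factor, factor_gene_map)
        unmapped = not any(g in expr for g in genes)
        if n < min_replicates:
            calls.append(CofactorCall(factor, n, None, None, "dropped_consensus", unmapped))
            continue
        if not is_expressed(genes, expr, min_mean, min_frac):
            calls.append(CofactorCall(factor, n, False, None, "dropped_expression", unmapped))
            continue
        coexpr = coexpressed_with_bait(genes, bait_gene, expr, min_mean, min_frac)
        verdict = "retained" if coexpr else "dropped_coexpression"
        calls.append(CofactorCall(factor, n, True, coexpr, verdict, unmapped))
    return calls


def write_cofactor_calls(calls: Sequence[CofactorCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("#factor\tn_replicates_supporting\texpressed\tcoexpressed_with_bait\tverdict\tunmapped\n")
        for c in calls:
            fmt = lambda v: "NA" if v is None else str(int(v))
            fh.write(
                f"{c.factor}\t{c.n_replicates_supporting}\t{fmt(c.expressed)}\t"
                f"{fmt(c.coexpressed_with_bait)}\t{c.verdict}\t{int(c.unmapped)}\n"
            )
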