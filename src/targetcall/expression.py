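"""Gene x cell-cluster expression summaries from single-cell data.

The pipeline never touches per-cell matrices: the unit of evidence is a
cluster-level summary with, per gene and cluster, the mean log-normalized
expression and the fraction of cells expressing.  A gene counts as
"expressed" in a cluster when either quantity clears its threshold
(defaults: mean >= 0.25 log-normalized units or >= 10% of cells).
"""

from __future__ import annotations

from typing import Iterable, Optional

import pandas as pd

DEFAULT_MIN_MEAN = 0.25
DEFAULT_MIN_FRAC = 0.10


class ExpressionSummary:
    """Paired gene x cluster matrices of mean expression and expressing fraction."""

    def __init__(self, mean: pd.DataFrame, frac: pd.DataFrame):
        if not mean.index.equals(frac.index) or not mean.columns.equals(frac.columns):
            raise ValueError("mean and frac matrices must share genes and cluster labels")
        if mean.index.has_duplicates:
            raise ValueError("duplicate gene ids in expression summary")
        if (mean.to_numpy() < 0).any():
            raise ValueError("mean expression must be non-negative")
        fr = frac.to_numpy()
        if (fr < 0).any() or (fr > 1).any():
            raise ValueError("expressing fractions must lie in [0, 1]")
        self.mean = mean.astype(float)
        self.frac = frac.astype(float)

    @property
    def genes(self) -> list[str]:
        return list(self.mean.index)

    @property
    def clusters(self) -> list[str]:
        return list(self.mean.columns)

    def __contains__(self, gene: str) -> bool:
        return gene in self.mean.index

    def expressed_clusters(
        self,
        gene: str,
        min_mean: float = DEFAULT_MIN_MEAN,
        min_frac: float = DEFAULT_MIN_FRAC,
    ) -> set[str]:
        """Clusters in which the gene clears either expression threshold."""
        m = self.mean.loc[gene]
        f = self.frac.loc[gene]
        return {c for c in self.clusters if m[c] >= min_mean or f[c] >= min_frac}

    # -- serialization: long-format TSV (gene_id, cluster, mean_expr, frac_expressing)

    def to_long(self) -> pd.DataFrame:
        rows = []
        for gene in self.genes:
            for cluster in self.clusters:
                rows.append(
                    (gene, cluster, self.mean.at[gene, cluster], self.frac.at[gene, cluster])
                )
        return pd.DataFrame(rows, columns=["gene_id", "cluster", "mean_expr", "frac_expressing"])

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "ExpressionSummary":
        mean = df.pivot(index="gene_id", columns="cluster", values="mean_expr")
        frac = df.pivot(index="gene_id", columns="cluster", values="frac_expressing")
        if mean.isna().any().any():
            missing = int(mean.isna().sum().sum())
            raise ValueError(f"expression summary is not a complete gene x cluster grid ({missing} missing cells)")
        # preserve first-appearance order of genes and clusters
        gene_order = list(dict.fromkeys(df["gene_id"]))
        cluster_order = list(dict.fromkeys(df["cluster"]))
        return cls(mean.loc[gene_order, cluster_order], frac.loc[gene_order, cluster_order])

    def write_tsv(self, path) -> None:
        long = self.to_long()
        with open(path, "w") as fh:
            fh.write("#gene_id\tcluster\tmean_expr\tfrac_expressing\n")
            for row in long.itertuples(index=False):
                fh.write(f"{row.gene_id}\t{row.cluster}\t{row.mean_expr:.6g}\t{row.frac_expressing:.6g}\n")

    @classmethod
    def read_tsv(cls, path) -> "ExpressionSummary":
        df = pd.read_csv(
            path,
            sep="\t",
            comment=None,
            names=["gene_id", "cluster", "mean_expr", "frac_expressing"],
            skiprows=1,
            dtype={"gene_id": str, "cluster": str},
        )
        return cls.from_long(df)
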