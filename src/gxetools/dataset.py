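"""Replicate-level FPKM expression container.

The central in-memory object is :class:`ExpressionDataset`: a long-format
table of replicate FPKM values for a two-genotype, multi-time-point design,
with one genotype designated the *reference* (the numerator of genotypic
log-ratios) and the first time-point acting as the untreated control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

REQUIRED_COLUMNS = ("gene_id", "genotype", "time_hr", "replicate", "fpkm")


@dataclass
class ExpressionDataset:
    """Replicate FPKM values indexed by gene x genotype x time-point.

    Parameters
    ----------
    data : pandas.DataFrame
        Long format with columns ``gene_id, genotype, time_hr, replicate,
        fpkm``.  FPKM must be non-negative.
    reference : str
        Genotype used as the numerator of genotypic difference (GD)
        log-ratios.
    alternate : str
        The other genotype (denominator of GD).
    time_points : tuple of float
        Ordered time-points in hours; the first is the control.
    """

    data: pd.DataFrame
    reference: str
    alternate: str
    time_points: tuple = field(default=())

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValidationError(f"missing required column(s): {missing}")
        neg = self.data.index[self.data["fpkm"] < 0]
        if len(neg):
            raise ValidationError(f"negative FPKM at row {neg[0]}")
        genos = set(self.data["genotype"].unique())
        if self.data.shape[0] and genos != {self.reference, self.alternate}:
            raise ValidationError(
                f"genotypes in data {sorted(genos)} do not match "
                f"reference={self.reference!r}, alternate={self.alternate!r}"
            )
        if not self.time_points:
            self.time_points = tuple(sorted(self.data["time_hr"].unique()))
        else:
            self.time_points = tuple(float(t) for t in self.time_points)
        if list(self.time_points) != sorted(set(self.time_points)):
            raise ValidationError("time_points must be strictly increasing")

    # -- basic accessors -------------------------------------------------

    @property
    def genotypes(self) -> tuple:
        return (self.reference, self.alternate)

    @property
    def control_time(self) -> float:
        return self.time_points[0]

    @property
    def gene_ids(self) -> list:
        return list(pd.unique(self.data["gene_id"]))

    @property
    def n_genes(self) -> int:
        return self.data["gene_id"].nunique()

    def __len__(self) -> int:
        return self.n_genes

    # -- summaries -------------------------------------------------------

    def cell_means(self) -> pd.DataFrame:
        """Replicate-mean FPKM per gene, one column per (genotype, time)."""
        return self.data.pivot_table(
            index="gene_id",
            columns=["genotype", "time_hr"],
            values="fpkm",
            aggfunc="mean",
        )

    def cell_cvs(self) -> pd.DataFrame:
        """Replicate coefficient of variation (sample sd / mean) per cell.

        NaN where fewer than 2 replicates or where the cell mean is 0
        (an undefined CV counts as a failing cell for the CV gate).
        """
        grouped = self.data.groupby(["gene_id", "genotype", "time_hr"])["fpkm"]
        stats = grouped.agg(["mean", "std", "count"])
        cv = stats["std"] / stats["mean"]
        cv[(stats["count"] < 2) | (stats["mean"] == 0)] = np.nan
        return cv.unstack(["genotype", "time_hr"])

    def replicate_values(self, gene_id, genotype, time_hr) -> np.ndarray:
        mask = (
            (self.data["gene_id"] == gene_id)
            & (self.data["genotype"] == genotype)
            & (self.data["time_hr"] == time_hr)
        )
        return self.data.loc[mask, "fpkm"].to_numpy()

    def log2_replicate_matrix(self, genotype, time_hr) -> pd.DataFrame:
        """log2(FPKM+1) replicates, genes x replicate, for one cell."""
        sub = self.data[
            (self.data["genotype"] == genotype) & (self.data["time_hr"] == time_hr)
        ]
        mat = sub.pivot_table(
            index="gene_id", columns="replicate", values="fpkm", aggfunc="first"
        )
        return np.log2(mat + 1.0)

    def subset(self, gene_ids) -> "ExpressionDataset":
        keep = self.data[self.data["gene_id"].isin(set(gene_ids))].reset_index(
            drop=True
        )
        return ExpressionDataset(
            keep, self.reference, self.alternate, self.time_points
        )
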