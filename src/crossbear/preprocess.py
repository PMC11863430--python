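"""Species demultiplexing of barnyard data and count-matrix QC filters.

In mixed-species combinatorial-indexing experiments a barcode can capture
cells of more than one species. After reads are mapped uniquely against a
concatenated multi-species reference (external pipeline), each cell carries
a per-species read count; a cell is a species doublet when the reads not
attributable to its top species exceed a fraction of its total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DOUBLET = "DOUBLET"
AMBIGUOUS = "AMBIGUOUS"

__all__ = ["DOUBLET", "AMBIGUOUS", "CellSpeciesCounts", "FilterConfig",
           "call_species", "call_species_table", "filter_matrix"]


@dataclass
class CellSpeciesCounts:
    cell_id: str
    counts: dict  # species -> non-negative integer read count

    def __post_init__(self):
        if not self.counts:
            raise ValueError("at least one species required")
        for v in self.counts.values():
            if v < 0 or v != int(v):
                raise ValueError("read counts must be non-negative integers")


@dataclass
class FilterConfig:
    doublet_fraction: float = 0.20
    min_cell_umi: int = 200
    min_cells_per_gene: int = 50
    mito_genes: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if not (0 < self.doublet_fraction < 1):
            raise ValueError("doublet_fraction must lie in (0, 1)")
        if self.min_cell_umi <= 0 or self.min_cells_per_gene <= 0:
            raise ValueError("thresholds must be positive")


def call_species(c: CellSpeciesCounts, cfg: FilterConfig | None = None) -> str:
    """Assign a species label, or DOUBLET / AMBIGUOUS.

    Sorts per-species read counts descending; when the sum of the second-
    and third-largest counts is strictly greater than ``doublet_fraction``
    of the total the cell is a doublet, otherwise it is labelled with the
    argmax species (AMBIGUOUS when the top two counts tie exactly).
    """
    cfg = cfg or FilterConfig()
    total = sum(c.counts.values())
    if total == 0:
        raise ValueError(f"cell {c.cell_id}: no reads in any species")
    if len(c.counts) == 1:
        return next(iter(c.counts))
    ordered = sorted(c.counts.items(), key=lambda kv: -kv[1])
    second = ordered[1][1]
    third = ordered[2][1] if len(ordered) > 2 else 0
    if second + third > cfg.doublet_fraction * total:
        return DOUBLET
    if ordered[0][1] == second:
        return AMBIGUOUS
    return ordered[0][0]


def call_species_table(df: pd.DataFrame, cfg: FilterConfig | None = None
                       ) -> pd.Series:
    """Vectorized species calls from a (cell_id, species, read_count) table."""
    wide = df.pivot_table(index="cell_id", columns="species",
                          values="read_count", fill_value=0, aggfunc="sum")
    return pd.Series(
        {cid: call_species(CellSpeciesCounts(cid, row.to_dict()), cfg)
         for cid, row in wide.iterrows()}, name="species_call")


def filter_matrix(counts: pd.DataFrame, cfg: FilterConfig,
                  ortholog_genes=None):
    """QC-filter a cell x gene count matrix; returns (filtered, report).

    Steps, in order: (1) keep only genes with cross-species orthologs,
    (2) drop mitochondrial genes, (3) drop cells with total UMI below
    ``min_cell_umi`` (depth counted after mito removal), (4) drop genes
    expressed (count > 0) in fewer than ``min_cells_per_gene`` cells pooled
    across datasets. The report records per-step removals.
    """
    report = {}
    out = counts

    if ortholog_genes is not None:
        keep = [g for g in out.columns if g in set(ortholog_genes)]
        report["genes_without_ortholog"] = out.shape[1] - len(keep)
        out = out[keep]
    else:
        report["genes_without_ortholog"] = 0

    mito = [g for g in out.columns if g in cfg.mito_genes]
    report["mitochondrial_genes"] = len(mito)
    out = out.drop(columns=mito)

    # iterate the cell- and gene-level filters to a fixed point so the whole
    # operation is idempotent (dropping sparse genes can push a cell's depth
    # below the UMI threshold, and vice versa)
    report["low_umi_cells"] = 0
    report["low_prevalence_genes"] = 0
    while True:
        keep_cells = out.sum(axis=1) >= cfg.min_cell_umi
        report["low_umi_cells"] += int((~keep_cells).sum())
        out = out.loc[keep_cells]
        keep_genes = (out > 0).sum(axis=0) >= cfg.min_cells_per_gene
        report["low_prevalence_genes"] += int((~keep_genes).sum())
        out = out.loc[:, keep_genes]
        if keep_cells.all() and keep_genes.all():
            break

    report["cells_kept"] = out.shape[0]
    report["genes_kept"] = out.shape[1]
    if out.size == 0:
        import warnings
        warnings.warn("all cells or genes removed by filtering")
    return out, report
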