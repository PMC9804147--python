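"""Single-cell QC filtering and depth normalization.

QC runs in one sequential pass: genes detected in fewer than 3 cells are
removed first; cells are then kept when they express 200-7500 genes
("expressed" = count > 0) and at most 10% of their reads map to
mitochondrial genes (identified by a configurable id prefix). Surviving
counts are log-normalized per cell: value = ln(1 + count * 10000 / total).
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .errors import ValidationError
from .tables_io import CellMatrix, ThresholdConfig


def qc_metrics(m: CellMatrix, cfg: ThresholdConfig):
    """Per-cell expressed-gene counts and mitochondrial read fraction."""
    counts = m.counts.tocsc()
    genes_per_cell = np.asarray((counts > 0).sum(axis=0)).ravel()
    total = np.asarray(counts.sum(axis=0)).ravel().astype(float)
    is_mito = np.array(
        [str(g).startswith(cfg.mito_prefix) for g in m.gene_ids], dtype=bool
    )
    mito = np.asarray(counts[is_mito].sum(axis=0)).ravel().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito / np.maximum(total, 1), 0.0)
    return genes_per_cell, mito_frac, total


def qc_filter(m: CellMatrix, cfg: ThresholdConfig | None = None) -> CellMatrix:
    """Apply the gene-then-cell QC pass; raises when nothing survives.

    Idempotent: a second application changes nothing, because every cell
    metric is recomputed on the gene-filtered matrix.
    """
    cfg = cfg or ThresholdConfig()
    cells_per_gene = np.asarray((m.counts > 0).sum(axis=1)).ravel()
    gene_keep = cells_per_gene >= cfg.qc_min_cells_per_gene
    if not gene_keep.any():
        raise ValidationError("QC removed every gene")
    g = m.subset(gene_mask=gene_keep)

    genes_per_cell, mito_frac, _ = qc_metrics(g, cfg)
    cell_keep = (
        (genes_per_cell >= cfg.qc_min_genes_per_cell)
        & (genes_per_cell <= cfg.qc_max_genes_per_cell)
        & (mito_frac <= cfg.qc_max_mito_frac)
    )
    if not cell_keep.any():
        raise ValidationError("QC removed every cell")
    return g.subset(cell_mask=cell_keep)


def normalize(m: CellMatrix, cfg: ThresholdConfig | None = None) -> CellMatrix:
    """Attach the log-normalized layer: ln(1 + count * norm_scale / cell total).

    Counts are left untouched. Cells with zero total cannot be normalized
    (they cannot occur after QC) and raise.
    """
    cfg = cfg or ThresholdConfig()
    counts = m.counts.tocsc().astype(float)
    totals = np.asarray(counts.sum(axis=0)).ravel()
    if (totals == 0).any():
        raise ValidationError("cannot normalize a cell with zero total counts")
    scaled = counts.multiply(cfg.norm_scale / totals)  # broadcasts per column
    norm = scaled.tocsr()
    norm.data = np.log1p(norm.data)
    return CellMatrix(
        counts=m.counts,
        gene_ids=m.gene_ids,
        cell_meta=m.cell_meta,
        normalized=norm,
    )


def prepare(m: CellMatrix, cfg: ThresholdConfig | None = None) -> CellMatrix:
    """QC then normalization, the standard preprocessing entry point."""
    cfg = cfg or ThresholdConfig()
    return normalize(qc_filter(m, cfg), cfg)


def qc_report(m: CellMatrix, cfg: ThresholdConfig | None = None):
    """Per-cell QC metrics with pass/fail reasons, for the CLI report."""
    import pandas as pd

    cfg = cfg or ThresholdConfig()
    cells_per_gene = np.asarray((m.counts > 0).sum(axis=1)).ravel()
    gene_keep = cells_per_gene >= cfg.qc_min_cells_per_gene
    g = m.subset(gene_mask=gene_keep)
    genes_per_cell, mito_frac, total = qc_metrics(g, cfg)
    df = pd.DataFrame(
        {
            "cell_id": g.cell_meta["cell_id"],
            "n_genes": genes_per_cell,
            "total_counts": total.astype(int),
            "mito_frac": mito_frac,
        }
    )
    df["fail_low_genes"] = df["n_genes"] < cfg.qc_min_genes_per_cell
    df["fail_high_genes"] = df["n_genes"] > cfg.qc_max_genes_per_cell
    df["fail_mito"] = df["mito_frac"] > cfg.qc_max_mito_frac
    df["pass"] = ~(df["fail_low_genes"] | df["fail_high_genes"] | df["fail_mito"])
    return df
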