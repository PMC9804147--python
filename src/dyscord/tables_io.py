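"""Readers, writers and domain containers for the pipeline's standard inputs.

Formats
-------
DE table      : TSV with header columns ``gene``, ``log2fc``, ``pvalue``, ``fdr``.
Universe      : plain text, one gene id per line.
Ortholog map  : two-column TSV (``source``, ``target``).
Counts        : Matrix Market coordinate integer file (genes x cells) with
                sidecar TSVs ``genes.tsv`` (gene_id) and ``cells.tsv``
                (cell_id, sample_id, line_id, cluster_label).
Config        : flat YAML key-value file mirroring :class:`ThresholdConfig`.

Gene identifiers are opaque, case-sensitive tokens everywhere except the
explicit case-convention heuristic :func:`default_symbol_map`.
"""

from __future__ import annotations

import dataclasses
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

DE_COLUMNS = ("gene", "log2fc", "pvalue", "fdr")


# ---------------------------------------------------------------------------
# DE tables
# ---------------------------------------------------------------------------

@dataclass
class DeTable:
    """One model's gene-level differential-expression results.

    ``df`` holds one row per tested gene with columns ``gene``, ``log2fc``
    (base-2 log of mutant/control expression), ``pvalue`` and ``fdr``
    (Benjamini-Hochberg adjusted). ``universe`` is the set of genes that
    passed the model's testing filter (e.g. total reads > 10 for bulk) and
    is the background population for overlap enrichment; it is a superset
    of the recorded genes.
    """

    model_id: str
    species: str
    df: pd.DataFrame
    universe: frozenset[str]

    def __post_init__(self) -> None:
        missing = [c for c in DE_COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"DE table missing column(s): {', '.join(missing)}")
        genes = self.df["gene"]
        if genes.duplicated().any():
            dups = genes[genes.duplicated()].unique()[:5]
            raise ValidationError(f"duplicate gene id(s) in DE table: {list(dups)}")
        if not self.universe:
            raise ValidationError("DE table universe is empty")
        extra = set(genes) - set(self.universe)
        if extra:
            raise ValidationError(
                f"{len(extra)} recorded gene(s) not in universe, e.g. {sorted(extra)[:5]}"
            )
        for col in ("pvalue", "fdr"):
            vals = self.df[col].to_numpy()
            if ((vals < 0) | (vals > 1)).any() or np.isnan(vals).any():
                raise ValidationError(f"{col} outside [0, 1]")
        if not np.isfinite(self.df["log2fc"].to_numpy()).all():
            raise ValidationError("non-finite log2fc")

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.df["gene"])

    def __len__(self) -> int:
        return len(self.df)


def read_de_table(
    path: str | Path,
    universe_path: str | Path | None = None,
    *,
    model_id: str | None = None,
    species: str = "",
) -> DeTable:
    """Read a DE table TSV, optionally with a separate universe file.

    Rows with non-finite log2fc or a p-value/FDR outside [0, 1] are
    rejected (dropped with a logged count). When no universe file is given
    the universe defaults to the table's own gene set.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    missing = [c for c in DE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing column(s): {', '.join(missing)}")
    df = df[list(DE_COLUMNS)].copy()
    for col in ("log2fc", "pvalue", "fdr"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    ok = (
        np.isfinite(df["log2fc"])
        & df["pvalue"].between(0, 1)
        & df["fdr"].between(0, 1)
    )
    if (~ok).any():
        logger.warning("%s: rejected %d malformed row(s)", path.name, int((~ok).sum()))
        df = df[ok].reset_index(drop=True)
    if universe_path is not None:
        universe = frozenset(read_universe(universe_path))
    else:
        universe = frozenset(df["gene"])
    return DeTable(
        model_id=model_id or path.stem,
        species=species,
        df=df,
        universe=universe,
    )


def write_de_table(table: DeTable, path: str | Path, universe_path: str | Path | None = None) -> None:
    table.df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    if universe_path is not None:
        write_universe(table.universe, universe_path)


def read_universe(path: str | Path) -> frozenset[str]:
    lines = Path(path).read_text().splitlines()
    genes = [ln.strip() for ln in lines if ln.strip()]
    if len(genes) != len(set(genes)):
        raise ValidationError(f"{Path(path).name}: duplicate ids in universe file")
    return frozenset(genes)


def write_universe(universe: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(universe)) + "\n")


# ---------------------------------------------------------------------------
# Ortholog maps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrthologMap:
    """1:1 correspondence between two id spaces (e.g. human and mouse symbols)."""

    pairs: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        src = [a for a, _ in self.pairs]
        tgt = [b for _, b in self.pairs]
        if len(set(src)) != len(src) or len(set(tgt)) != len(tgt):
            raise ValidationError("ortholog map is not 1:1 after restriction")

    def __len__(self) -> int:
        return len(self.pairs)

    def as_dict(self) -> dict[str, str]:
        return dict(self.pairs)

    def inverse(self) -> dict[str, str]:
        return {b: a for a, b in self.pairs}


def restrict_one_to_one(pairs: Sequence[tuple[str, str]]) -> OrthologMap:
    """Drop every pair whose source or target participates in >1 pair."""
    pairs = list(dict.fromkeys(pairs))
    src_counts = Counter(a for a, _ in pairs)
    tgt_counts = Counter(b for _, b in pairs)
    kept = tuple(
        (a, b) for a, b in pairs if src_counts[a] == 1 and tgt_counts[b] == 1
    )
    dropped = len(pairs) - len(kept)
    if dropped:
        logger.info("ortholog map: dropped %d non-1:1 pair(s)", dropped)
    return OrthologMap(kept)


def read_ortholog_map(path: str | Path) -> OrthologMap:
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] != 2:
        raise FormatError(f"{Path(path).name}: expected 2 columns, got {df.shape[1]}")
    return restrict_one_to_one(list(df.itertuples(index=False, name=None)))


def write_ortholog_map(omap: OrthologMap, path: str | Path) -> None:
    pd.DataFrame(list(omap.pairs), columns=["source", "target"]).to_csv(
        path, sep="\t", index=False
    )


def default_symbol_map(
    human_ids: Iterable[str], mouse_ids: Iterable[str]
) -> OrthologMap:
    """Heuristic human<->mouse symbol map by case-insensitive equality.

    Human symbols are conventionally upper-case (CDKN1A), mouse title-case
    (Cdkn1a); this matches them on casefolded identity and keeps only 1:1
    matches. A principled ortholog table should be preferred when available.
    """
    human_by_key: dict[str, list[str]] = {}
    for h in human_ids:
        human_by_key.setdefault(h.casefold(), []).append(h)
    mouse_by_key: dict[str, list[str]] = {}
    for m in mouse_ids:
        mouse_by_key.setdefault(m.casefold(), []).append(m)
    pairs = []
    for key, hs in human_by_key.items():
        ms = mouse_by_key.get(key, [])
        if len(hs) == 1 and len(ms) == 1:
            pairs.append((hs[0], ms[0]))
    return restrict_one_to_one(pairs)


# ---------------------------------------------------------------------------
# Annotated count matrices
# ---------------------------------------------------------------------------

CELL_META_COLUMNS = ("cell_id", "sample_id", "line_id", "cluster_label")


@dataclass
class CellMatrix:
    """Genes x cells integer counts with per-cell sample/line/cluster labels.

    ``cell_meta`` is indexed positionally in cell order and carries the
    columns cell_id, sample_id, line_id, cluster_label. ``normalized`` is an
    optional same-shape layer of log-normalized expression values.
    """

    counts: sp.csr_matrix
    gene_ids: pd.Index
    cell_meta: pd.DataFrame
    normalized: sp.csr_matrix | None = None

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = pd.Index(self.gene_ids, dtype=object)
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise ValidationError(
                f"gene sidecar has {len(self.gene_ids)} rows for {n_genes} matrix rows"
            )
        if len(self.cell_meta) != n_cells:
            raise ValidationError(
                f"cell sidecar has {len(self.cell_meta)} rows for {n_cells} matrix columns"
            )
        missing = [c for c in CELL_META_COLUMNS if c not in self.cell_meta.columns]
        if missing:
            raise FormatError(f"cell metadata missing column(s): {', '.join(missing)}")
        if self.cell_meta[list(CELL_META_COLUMNS)].isna().any().any():
            raise ValidationError("cell metadata contains missing labels")
        if self.gene_ids.duplicated().any():
            raise ValidationError("duplicate gene ids")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValidationError("negative counts")
        if self.counts.nnz and not np.allclose(self.counts.data, np.round(self.counts.data)):
            raise ValidationError("non-integral counts")
        if self.normalized is not None and self.normalized.shape != self.counts.shape:
            raise ValidationError("normalized layer shape mismatch")
        self.cell_meta = self.cell_meta.reset_index(drop=True)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def subset(self, gene_mask=None, cell_mask=None) -> "CellMatrix":
        gm = np.arange(self.n_genes) if gene_mask is None else np.asarray(gene_mask)
        cm = np.arange(self.n_cells) if cell_mask is None else np.asarray(cell_mask)
        if gm.dtype == bool:
            gm = np.flatnonzero(gm)
        if cm.dtype == bool:
            cm = np.flatnonzero(cm)
        return CellMatrix(
            counts=self.counts[gm][:, cm],
            gene_ids=self.gene_ids[gm],
            cell_meta=self.cell_meta.iloc[cm].reset_index(drop=True),
            normalized=None if self.normalized is None else self.normalized[gm][:, cm],
        )

    def cells_where(self, **labels: str) -> np.ndarray:
        """Positional indices of cells matching all given label equalities."""
        mask = np.ones(self.n_cells, dtype=bool)
        for col, val in labels.items():
            mask &= (self.cell_meta[col] == val).to_numpy()
        return np.flatnonzero(mask)

    def to_anndata(self):
        """Cells x genes AnnData view (counts in X, normalized as a layer)."""
        import anndata as ad

        adata = ad.AnnData(
            X=self.counts.T.tocsr(),
            obs=self.cell_meta.set_index("cell_id"),
            var=pd.DataFrame(index=pd.Index(self.gene_ids, name="gene_id")),
        )
        if self.normalized is not None:
            adata.layers["lognorm"] = self.normalized.T.tocsr()
        return adata


def read_counts(
    mtx_path: str | Path, genes_path: str | Path, cells_path: str | Path
) -> CellMatrix:
    """Read a Matrix Market triplet file with gene/cell sidecar TSVs."""
    mat = scipy.io.mmread(str(mtx_path))
    genes = pd.read_csv(genes_path, sep="\t", dtype=str)
    if "gene_id" not in genes.columns:
        raise FormatError(f"{Path(genes_path).name}: missing column gene_id")
    cells = pd.read_csv(cells_path, sep="\t", dtype=str)
    missing = [c for c in CELL_META_COLUMNS if c not in cells.columns]
    if missing:
        raise FormatError(f"{Path(cells_path).name}: missing column(s): {', '.join(missing)}")
    return CellMatrix(
        counts=sp.csr_matrix(mat, dtype=np.int64),
        gene_ids=pd.Index(genes["gene_id"]),
        cell_meta=cells,
    )


def write_counts(
    m: CellMatrix, mtx_path: str | Path, genes_path: str | Path, cells_path: str | Path
) -> None:
    scipy.io.mmwrite(str(mtx_path), sp.coo_matrix(m.counts), field="integer")
    pd.DataFrame({"gene_id": m.gene_ids}).to_csv(genes_path, sep="\t", index=False)
    m.cell_meta[list(CELL_META_COLUMNS)].to_csv(cells_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Threshold configuration
# ---------------------------------------------------------------------------

@dataclass
class ThresholdConfig:
    """All analysis thresholds in one place.

    Defaults follow the study design: DEGs require |log2fc| > 0.25 with
    FDR < 0.05; tables with fewer than 10 FDR DEGs fall back to raw
    p < 0.05; single-cell QC keeps genes in >= 3 cells and cells with
    200-7500 expressed genes and <= 10% mitochondrial reads; expression is
    log-normalized to 10,000 transcripts per cell; burden analysis uses
    clusters with > 10 cells in every sample, downsampled to a common cell
    number over 10 iterations.
    """

    lfc_min: float = 0.25
    fdr_max: float = 0.05
    min_pct: float = 0.05
    fallback_min_degs: int = 10
    fallback_p: float = 0.05
    qc_min_cells_per_gene: int = 3
    qc_min_genes_per_cell: int = 200
    qc_max_genes_per_cell: int = 7500
    qc_max_mito_frac: float = 0.10
    norm_scale: float = 10_000.0
    burden_min_cells: int = 10
    burden_k: int | str = "auto"
    burden_iters: int = 10
    mito_prefix: str = "MT-"

    def __post_init__(self) -> None:
        positives = {
            "lfc_min": self.lfc_min,
            "fdr_max": self.fdr_max,
            "min_pct": self.min_pct,
            "fallback_min_degs": self.fallback_min_degs,
            "fallback_p": self.fallback_p,
            "qc_min_cells_per_gene": self.qc_min_cells_per_gene,
            "qc_min_genes_per_cell": self.qc_min_genes_per_cell,
            "qc_max_genes_per_cell": self.qc_max_genes_per_cell,
            "qc_max_mito_frac": self.qc_max_mito_frac,
            "norm_scale": self.norm_scale,
            "burden_min_cells": self.burden_min_cells,
            "burden_iters": self.burden_iters,
        }
        for name, val in positives.items():
            if not val > 0:
                raise ValidationError(f"{name} must be positive, got {val}")
        for name, val in (
            ("fdr_max", self.fdr_max),
            ("fallback_p", self.fallback_p),
            ("min_pct", self.min_pct),
            ("qc_max_mito_frac", self.qc_max_mito_frac),
        ):
            if not 0 < val < 1:
                raise ValidationError(f"{name} must be in (0, 1), got {val}")
        if self.burden_k != "auto" and (
            not isinstance(self.burden_k, int) or self.burden_k <= 0
        ):
            raise ValidationError("burden_k must be 'auto' or a positive integer")


def read_config(path: str | Path) -> ThresholdConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise FormatError("config file must be a flat key-value mapping")
    known = {f.name for f in dataclasses.fields(ThresholdConfig)}
    unknown = set(raw) - known
    if unknown:
        raise FormatError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    return ThresholdConfig(**raw)


def write_config(cfg: ThresholdConfig, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(dataclasses.asdict(cfg), sort_keys=True, default_flow_style=False)
    )
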