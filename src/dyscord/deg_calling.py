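"""Direction-specific DEG calling with the low-power fallback rule.

A gene is differentially expressed when its |log2fc| strictly exceeds
``lfc_min`` and its significance column is strictly below its cutoff. The
significance column is the BH-adjusted FDR unless the table yields fewer
than ``fallback_min_degs`` FDR-qualifying genes, in which case the raw
p-value at ``fallback_p`` is used instead (the low-power fallback applied
to the perinatal mouse models). Two replicate models (e.g. two isogenic
mutant lines) are combined by intersecting their per-direction DEG sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .tables_io import DeTable, ThresholdConfig

logger = logging.getLogger(__name__)

Direction = Literal["up", "down"]
PMode = Literal["fdr", "raw"]


@dataclass(frozen=True)
class DegSet:
    """A direction-specific DEG set with the thresholds that produced it."""

    direction: Direction
    genes: frozenset[str]
    source_model: str
    p_mode: PMode
    lfc_min: float
    p_cutoff: float

    def __len__(self) -> int:
        return len(self.genes)


def n_fdr_degs(table: DeTable, cfg: ThresholdConfig) -> int:
    """Count of genes qualifying at FDR < fdr_max and |log2fc| > lfc_min."""
    fdr = table.df["fdr"].to_numpy()
    lfc = table.df["log2fc"].to_numpy()
    return int(((fdr < cfg.fdr_max) & (np.abs(lfc) > cfg.lfc_min)).sum())


def effective_p_mode(table: DeTable, cfg: ThresholdConfig) -> PMode:
    """``raw`` iff the table has fewer than ``fallback_min_degs`` FDR DEGs."""
    return "raw" if n_fdr_degs(table, cfg) < cfg.fallback_min_degs else "fdr"


def extract_degs(
    table: DeTable, direction: Direction, cfg: ThresholdConfig
) -> DegSet:
    """Genes passing the direction-specific fold-change and significance cuts.

    All inequalities are strict: a gene at log2fc exactly ``lfc_min`` or a
    p-value exactly at its cutoff is excluded.
    """
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    mode = effective_p_mode(table, cfg)
    if mode == "fdr":
        p = table.df["fdr"].to_numpy()
        cutoff = cfg.fdr_max
    else:
        p = table.df["pvalue"].to_numpy()
        cutoff = cfg.fallback_p
    lfc = table.df["log2fc"].to_numpy()
    if direction == "up":
        keep = (lfc > cfg.lfc_min) & (p < cutoff)
    else:
        keep = (lfc < -cfg.lfc_min) & (p < cutoff)
    return DegSet(
        direction=direction,
        genes=frozenset(table.df.loc[keep, "gene"]),
        source_model=table.model_id,
        p_mode=mode,
        lfc_min=cfg.lfc_min,
        p_cutoff=cutoff,
    )


def shared_degs(
    table_a: DeTable, table_b: DeTable, cfg: ThresholdConfig
) -> tuple[DegSet, DegSet]:
    """DEGs called in the same direction in both tables.

    A gene up in one table and down in the other appears in neither output.
    Symmetric in the two tables.
    """
    if not (table_a.universe & table_b.universe):
        logger.warning(
            "shared_degs: universes of %s and %s are disjoint",
            table_a.model_id,
            table_b.model_id,
        )
    label = f"{table_a.model_id}&{table_b.model_id}"
    out = []
    for direction in ("up", "down"):
        da = extract_degs(table_a, direction, cfg)
        db = extract_degs(table_b, direction, cfg)
        out.append(
            DegSet(
                direction=direction,
                genes=da.genes & db.genes,
                source_model=label,
                p_mode="fdr" if (da.p_mode == db.p_mode == "fdr") else "raw",
                lfc_min=cfg.lfc_min,
                p_cutoff=min(da.p_cutoff, db.p_cutoff),
            )
        )
    return out[0], out[1]
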