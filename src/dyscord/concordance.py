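"""Cross-model concordance: quadrant enrichment, regression sweep, sign test.

Two DE tables are joined through a 1:1 ortholog map; the joint universe is
the set of mapped gene pairs whose members were testable in both models.
Overlap of direction-specific DEG sets is summarised by the geometric mean
enrichment (GME): observed / expected overlap given the universe,

    fold = n11 * U / ((n11 + n10) * (n11 + n01)),

algebraically the geometric mean of the two conditional enrichments, with a
one-sided (greater) Fisher exact p-value on the 2x2 table
[[n11, n10], [n01, n00]] where n00 counts genes in neither set. Effect-size
agreement is quantified by ordinary least squares of model-B log2fc on
model-A log2fc over model-A's DEGs, optionally restricted by a significance
threshold on model B, swept loose to strict. Genes dysregulated in opposite
directions are probed with an exact two-sided binomial sign test against a
third model's raw fold changes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .deg_calling import DegSet
from .errors import ValidationError
from .tables_io import DeTable, OrthologMap

logger = logging.getLogger(__name__)

# A y-axis significance filter: None, ("raw", alpha) or ("fdr", alpha).
Threshold = tuple[str, float] | None


@dataclass(frozen=True)
class JoinedPair:
    """Ortholog-joined DE results for two models.

    ``df`` is indexed by model-A gene id with columns gene_b, log2fc_a,
    pvalue_a, fdr_a, log2fc_b, pvalue_b, fdr_b. ``universe`` is the joint
    background: mapped pairs testable in both models, in model-A id space.
    """

    model_a: str
    model_b: str
    df: pd.DataFrame
    universe: frozenset[str]
    b_to_a: Mapping[str, str]

    def map_b_genes(self, genes: Iterable[str]) -> frozenset[str]:
        """Translate model-B gene ids into model-A id space via the map."""
        return frozenset(self.b_to_a[g] for g in genes if g in self.b_to_a)


@dataclass(frozen=True)
class QuadrantTable:
    """2x2 overlap counts over a joint universe of size U."""

    n11: int
    n10: int
    n01: int
    n00: int
    label: str = ""

    def __post_init__(self) -> None:
        if min(self.n11, self.n10, self.n01, self.n00) < 0:
            raise ValidationError("negative quadrant count")

    @property
    def U(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00


@dataclass(frozen=True)
class GmeResult:
    """Geometric mean enrichment of a DEG-set overlap."""

    fold: float  # observed/expected overlap; NaN when a marginal is empty
    pvalue: float  # one-sided (greater) Fisher exact p
    odds_ratio: float  # Fisher conditional odds ratio, for transparency
    quadrant: QuadrantTable
    genes_overlap: frozenset[str] = frozenset()


@dataclass(frozen=True)
class FitResult:
    """Least-squares fit of model-B log2fc on model-A log2fc."""

    slope: float
    intercept: float
    r2: float
    n_genes: int
    threshold_label: str

    @property
    def defined(self) -> bool:
        return self.n_genes >= 3 and math.isfinite(self.slope)


@dataclass(frozen=True)
class SignConsistency:
    """Agreement of raw fold-change signs with a queried direction."""

    n_agree: int
    n_total: int
    p_binomial: float


# ---------------------------------------------------------------------------
# Join
# ---------------------------------------------------------------------------

def join_on_orthologs(
    table_a: DeTable, table_b: DeTable, omap: OrthologMap
) -> JoinedPair:
    """Join two DE tables through a 1:1 ortholog map.

    The joint universe keeps a mapped pair only when both members are in
    their table's universe; joined records additionally require a recorded
    row in both tables.
    """
    fwd = omap.as_dict()
    universe = frozenset(
        a for a, b in omap.pairs if a in table_a.universe and b in table_b.universe
    )
    if not universe:
        raise ValidationError(
            f"empty joint universe between {table_a.model_id} and {table_b.model_id}"
        )
    a = table_a.df.rename(
        columns={"log2fc": "log2fc_a", "pvalue": "pvalue_a", "fdr": "fdr_a"}
    )
    a = a[a["gene"].isin(universe)].copy()
    a["gene_b"] = a["gene"].map(fwd)
    b = table_b.df.rename(
        columns={
            "gene": "gene_b",
            "log2fc": "log2fc_b",
            "pvalue": "pvalue_b",
            "fdr": "fdr_b",
        }
    )
    df = a.merge(b, on="gene_b", how="inner").set_index("gene")
    b_to_a = {fwd[g]: g for g in universe}
    return JoinedPair(
        model_a=table_a.model_id,
        model_b=table_b.model_id,
        df=df,
        universe=universe,
        b_to_a=b_to_a,
    )


# ---------------------------------------------------------------------------
# Quadrant overlap enrichment
# ---------------------------------------------------------------------------

def quadrant_counts(
    genes_a: Iterable[str],
    genes_b: Iterable[str],
    joint_universe: Iterable[str],
    label: str = "",
) -> QuadrantTable:
    """Overlap contingency of two gene sets over a background universe.

    Both sets are intersected with the universe before counting; n00 counts
    universe genes in neither set (standard complement construction).
    """
    universe = set(joint_universe)
    a = set(genes_a) & universe
    b = set(genes_b) & universe
    n11 = len(a & b)
    n10 = len(a - b)
    n01 = len(b - a)
    n00 = len(universe) - n11 - n10 - n01
    return QuadrantTable(n11, n10, n01, n00, label=label)


def gme(q: QuadrantTable, genes_overlap: frozenset[str] = frozenset()) -> GmeResult:
    """Geometric mean enrichment with a one-sided Fisher exact test.

    Fold is undefined (NaN, p = 1) when either DEG-set marginal is empty.
    """
    size_a = q.n11 + q.n10
    size_b = q.n11 + q.n01
    if size_a == 0 or size_b == 0:
        return GmeResult(float("nan"), 1.0, float("nan"), q, genes_overlap)
    fold = q.n11 * q.U / (size_a * size_b)
    odds, p = stats.fisher_exact(
        [[q.n11, q.n10], [q.n01, q.n00]], alternative="greater"
    )
    return GmeResult(float(fold), float(p), float(odds), q, genes_overlap)


def gme_all_quadrants(
    degs_up_a: DegSet,
    degs_down_a: DegSet,
    degs_up_b: DegSet,
    degs_down_b: DegSet,
    joint_universe: Iterable[str],
) -> dict[str, GmeResult]:
    """GME for every direction combination (up-up, down-down, up-down, down-up).

    All DEG sets must already share one id space (model-B sets translated
    through the ortholog map).
    """
    universe = set(joint_universe)
    combos = {
        "up-up": (degs_up_a.genes, degs_up_b.genes),
        "down-down": (degs_down_a.genes, degs_down_b.genes),
        "up-down": (degs_up_a.genes, degs_down_b.genes),
        "down-up": (degs_down_a.genes, degs_up_b.genes),
    }
    out = {}
    for label, (ga, gb) in combos.items():
        q = quadrant_counts(ga, gb, universe, label=label)
        overlap = frozenset((set(ga) & set(gb)) & universe)
        out[label] = gme(q, genes_overlap=overlap)
    return out


# ---------------------------------------------------------------------------
# Fold-change regression and threshold sweep
# ---------------------------------------------------------------------------

def _threshold_label(threshold: Threshold) -> str:
    if threshold is None:
        return "none"
    kind, alpha = threshold
    return f"{kind}<{alpha:g}"


def lfc_regression(
    joined: JoinedPair, x_genes: Iterable[str], y_threshold: Threshold = None
) -> FitResult:
    """OLS of model-B log2fc on model-A log2fc over model-A's DEGs.

    ``x_genes`` is the pooled (both-direction) DEG set of model A in A id
    space; ``y_threshold`` optionally restricts to genes significant in
    model B (("raw", a) or ("fdr", a), strict inequality). Fits with fewer
    than 3 points are flagged undefined.
    """
    df = joined.df.loc[joined.df.index.isin(set(x_genes))]
    if y_threshold is not None:
        kind, alpha = y_threshold
        if kind not in ("raw", "fdr"):
            raise ValueError(f"unknown threshold kind {kind!r}")
        col = "pvalue_b" if kind == "raw" else "fdr_b"
        df = df[df[col] < alpha]
    label = _threshold_label(y_threshold)
    n = len(df)
    if n < 3 or df["log2fc_a"].nunique() < 2:
        logger.warning("lfc_regression: undefined fit (n=%d) at %s", n, label)
        return FitResult(float("nan"), float("nan"), float("nan"), n, label)
    fit = stats.linregress(df["log2fc_a"], df["log2fc_b"])
    return FitResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue**2),
        n_genes=n,
        threshold_label=label,
    )


def threshold_sweep(
    joined: JoinedPair,
    x_genes: Iterable[str],
    thresholds: Sequence[Threshold] = (None, ("fdr", 0.5), ("fdr", 0.05)),
) -> list[FitResult]:
    """One fit per y-axis threshold, ordered loose to strict."""
    x_genes = set(x_genes)
    return [lfc_regression(joined, x_genes, t) for t in thresholds]


# ---------------------------------------------------------------------------
# Sign consistency
# ---------------------------------------------------------------------------

def sign_consistency(
    directions: Mapping[str, str], target: DeTable
) -> SignConsistency:
    """Fraction of genes whose raw target log2fc sign matches a query.

    ``directions`` maps gene id (in the target table's id space) to the
    queried direction ("up" or "down"). A log2fc of exactly zero counts as
    disagreement; genes missing from the target table are dropped with a
    logged count. Significance is an exact two-sided binomial test at 0.5.
    """
    lfc = target.df.set_index("gene")["log2fc"]
    present = {g: d for g, d in directions.items() if g in lfc.index}
    if len(present) < len(directions):
        logger.info(
            "sign_consistency: dropped %d gene(s) missing from %s",
            len(directions) - len(present),
            target.model_id,
        )
    n_total = len(present)
    n_agree = 0
    for g, d in present.items():
        if d not in ("up", "down"):
            raise ValueError(f"direction must be 'up' or 'down', got {d!r}")
        v = lfc.loc[g]
        n_agree += (v > 0) if d == "up" else (v < 0)
    if n_total == 0:
        return SignConsistency(0, 0, 1.0)
    p = stats.binomtest(n_agree, n_total, 0.5, alternative="two-sided").pvalue
    return SignConsistency(int(n_agree), n_total, float(p))
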