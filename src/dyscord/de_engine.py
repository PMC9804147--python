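"""Rank-based differential expression over normalized single-cell values.

This engine exists for the downsampled burden procedure and for synthetic
line-vs-control calls: per gene it compares the two cell groups' normalized
expression with a two-sided Wilcoxon rank-sum test (exact by enumeration
when both groups have at most 8 cells, normal approximation with tie and
continuity corrections otherwise) and reports a mean-based log2 fold
change. Genes are pre-filtered exactly the way the study's external engine
was configured: a gene is tested only if expressed in at least ``min_pct``
of either group's cells and its |log2fc| exceeds ``lfc_min``; BH adjustment
runs over the tested genes only, and the recorded universe is the
min_pct-passing set. It deliberately does not refit the hurdle model with
latent covariates used upstream on real data — for real datasets, externally
produced DE tables are the authoritative input.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .tables_io import CellMatrix, DeTable, ThresholdConfig

EXACT_MAX_N = 8


# ---------------------------------------------------------------------------
# Primitives
# ---------------------------------------------------------------------------

def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Monotone (non-decreasing in the raw p ordering), elementwise >= raw,
    capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValidationError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(n)
    out[order] = adjusted
    return out


def log2fc_means(values_a: np.ndarray, values_b: np.ndarray) -> float:
    """log2((mA + 1) / (mB + 1)) of mean depth-corrected expression per 10k.

    Inputs are normalized (log1p) values; expm1 recovers counts-per-10k
    before averaging, so the effect size is on the depth-corrected scale.
    Antisymmetric under group swap; zero for identical groups.
    """
    ma = float(np.mean(np.expm1(values_a)))
    mb = float(np.mean(np.expm1(values_b)))
    return float(np.log2((ma + 1.0) / (mb + 1.0)))


@lru_cache(maxsize=16)
def _labelings(n: int, n_a: int) -> np.ndarray:
    """All C(n, n_a) group-A index choices, as an array for vectorized sums."""
    return np.array(list(combinations(range(n), n_a)), dtype=np.intp)


def _rank_sum_exact(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided p by enumerating all group-A labelings of the pooled values.

    p = P(|W - mu| >= |w_obs - mu|) where W is the rank sum of group A over
    uniformly random labelings and mu its mean; ties handled by midranks.
    """
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n_a = len(a)
    w_obs = ranks[:n_a].sum()
    mu = n_a * (len(pooled) + 1) / 2.0
    d_obs = abs(w_obs - mu)
    w = ranks[_labelings(len(pooled), n_a)].sum(axis=1)
    hits = int((np.abs(w - mu) >= d_obs - 1e-12).sum())
    return hits / comb(len(pooled), n_a)


def rank_test(values_a, values_b) -> float:
    """Two-sided Wilcoxon rank-sum p-value for two cell groups.

    Exact enumeration when both groups have <= 8 values; otherwise the
    normal approximation with tie correction and continuity correction.
    Degenerate all-tied input returns p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("rank_test requires at least one value per group")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    if a.size <= EXACT_MAX_N and b.size <= EXACT_MAX_N:
        return _rank_sum_exact(a, b)
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# Full engine
# ---------------------------------------------------------------------------

@dataclass
class DeEngineResult:
    """A DeTable of tested genes plus per-gene detection fractions.

    ``table`` records only the tested genes (those passing both the
    detection and fold-change pre-filters); its universe is every gene
    passing the detection filter alone. ``per_gene`` reports log2fc,
    detection fractions and the tested flag for all genes.
    """

    table: DeTable
    per_gene: pd.DataFrame

    def deg_count(self, cfg: ThresholdConfig) -> int:
        """Both-direction DEG count at FDR < fdr_max (tested genes already
        satisfy |log2fc| > lfc_min)."""
        return int((self.table.df["fdr"] < cfg.fdr_max).sum())


def run_de(
    m: CellMatrix,
    cells_a,
    cells_b,
    cfg: ThresholdConfig | None = None,
    *,
    model_id: str = "de",
) -> DeEngineResult:
    """Rank-based DE of cell group A (e.g. mutant) versus group B (control).

    Groups are positional cell indices and must be disjoint and non-empty.
    Requires the normalized layer (see :func:`dyscord.sc_prep.normalize`).
    """
    cfg = cfg or ThresholdConfig()
    if m.normalized is None:
        raise ValidationError("run_de requires a normalized layer; run sc_prep first")
    ia = np.asarray(cells_a, dtype=int)
    ib = np.asarray(cells_b, dtype=int)
    if ia.size == 0 or ib.size == 0:
        raise ValidationError("both cell groups must be non-empty")
    if np.intersect1d(ia, ib).size:
        raise ValidationError("cell groups overlap")

    counts_a = m.counts[:, ia]
    counts_b = m.counts[:, ib]
    pct_a = np.asarray((counts_a > 0).sum(axis=1)).ravel() / ia.size
    pct_b = np.asarray((counts_b > 0).sum(axis=1)).ravel() / ib.size
    in_universe = np.maximum(pct_a, pct_b) >= cfg.min_pct

    norm_a = np.asarray(m.normalized[:, ia].todense())
    norm_b = np.asarray(m.normalized[:, ib].todense())
    mean_a = np.expm1(norm_a).mean(axis=1)
    mean_b = np.expm1(norm_b).mean(axis=1)
    lfc = np.log2((mean_a + 1.0) / (mean_b + 1.0))

    tested = in_universe & (np.abs(lfc) > cfg.lfc_min)
    tested_idx = np.flatnonzero(tested)

    if ia.size <= EXACT_MAX_N and ib.size <= EXACT_MAX_N:
        pvals = np.array(
            [rank_test(norm_a[i], norm_b[i]) for i in tested_idx]
        )
    elif tested_idx.size:
        degenerate = np.array(
            [
                np.all(
                    np.concatenate([norm_a[i], norm_b[i]])
                    == norm_a[i, 0]
                )
                for i in tested_idx
            ]
        )
        pvals = np.ones(tested_idx.size)
        live = ~degenerate
        if live.any():
            res = stats.mannwhitneyu(
                norm_a[tested_idx[live]],
                norm_b[tested_idx[live]],
                alternative="two-sided",
                method="asymptotic",
                use_continuity=True,
                axis=1,
            )
            pvals[live] = res.pvalue
    else:
        pvals = np.array([])

    fdr = bh_adjust(pvals)
    gene_ids = np.asarray(m.gene_ids, dtype=object)
    table = DeTable(
        model_id=model_id,
        species="",
        df=pd.DataFrame(
            {
                "gene": gene_ids[tested_idx],
                "log2fc": lfc[tested_idx],
                "pvalue": pvals,
                "fdr": fdr,
            }
        ),
        universe=frozenset(gene_ids[in_universe]),
    )
    per_gene = pd.DataFrame(
        {
            "gene": gene_ids,
            "log2fc": lfc,
            "pct_group_a": pct_a,
            "pct_group_b": pct_b,
            "in_universe": in_universe,
            "tested": tested,
        }
    )
    return DeEngineResult(table=table, per_gene=per_gene)
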