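"""Cluster-downsampled DEG burden and cell-type composition comparison.

Burden ranks cell clusters by how transcriptomically disrupted a mutant
line is: clusters present with more than ``burden_min_cells`` cells in
every sample are downsampled to a common cell number k per (cluster,
sample), the line's samples are pooled against the control's per cluster,
DEGs are counted (|log2fc| > 0.25, FDR < 0.05, both directions) and the
count is averaged over ``burden_iters`` independent downsampling
iterations. Composition compares per-cluster cell proportions between a
line and the control: per-sample proportions give mean +/- SEM for
reporting, while significance comes from a two-sided Fisher exact test on
the pooled [in-cluster, out-of-cluster] x [line, control] counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .de_engine import run_de
from .errors import ValidationError
from .tables_io import CellMatrix, ThresholdConfig


@dataclass
class BurdenResult:
    """Averaged downsampled DEG counts per eligible cluster for one line."""

    mutant_line: str
    control_line: str
    iteration_counts: dict[str, list[int]]  # cluster -> one count per iteration
    k_used: int
    eligible_clusters: list[str]
    seed: int

    @property
    def mean_counts(self) -> dict[str, float]:
        return {c: float(np.mean(v)) for c, v in self.iteration_counts.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cluster, counts in self.iteration_counts.items():
            rows.append(
                {
                    "cluster": cluster,
                    "mean_degs": float(np.mean(counts)),
                    "sem_degs": float(np.std(counts, ddof=1) / np.sqrt(len(counts)))
                    if len(counts) > 1
                    else 0.0,
                    "iterations": len(counts),
                    "k": self.k_used,
                }
            )
        return pd.DataFrame(rows).sort_values("mean_degs", ascending=False).reset_index(drop=True)


@dataclass
class CompositionResult:
    """Per-cluster composition comparison of one line against the control."""

    line: str
    control_line: str
    per_cluster: pd.DataFrame  # cluster, pooled counts, fisher p, direction
    per_sample: pd.DataFrame  # sample x cluster proportions (rows sum to 1)


def cluster_sample_counts(m: CellMatrix) -> pd.DataFrame:
    """Cells per (cluster, sample) as a clusters x samples table."""
    return pd.crosstab(m.cell_meta["cluster_label"], m.cell_meta["sample_id"])


def eligible_clusters(
    m: CellMatrix, cfg: ThresholdConfig | None = None
) -> tuple[list[str], int]:
    """Clusters with > burden_min_cells cells in every sample, and k.

    k is the minimum (eligible cluster, sample) cell count, unless the
    config pins an explicit ``burden_k``.
    """
    cfg = cfg or ThresholdConfig()
    table = cluster_sample_counts(m)
    keep = table.min(axis=1) > cfg.burden_min_cells
    clusters = sorted(table.index[keep])
    if not clusters:
        raise ValidationError(
            f"no cluster exceeds {cfg.burden_min_cells} cells in every sample"
        )
    if cfg.burden_k == "auto":
        k = int(table.loc[clusters].min().min())
    else:
        k = int(cfg.burden_k)
    return clusters, k


def downsample(
    m: CellMatrix, cluster: str, sample: str, k: int, rng: np.random.Generator
) -> np.ndarray:
    """k distinct cell indices sampled uniformly from a (cluster, sample).

    Deterministic given the generator state; returns the full group (sorted)
    when k equals the group size.
    """
    idx = m.cells_where(cluster_label=cluster, sample_id=sample)
    if idx.size < k:
        raise ValidationError(
            f"cluster {cluster!r} sample {sample!r} has {idx.size} cells < k={k}"
        )
    if idx.size == k:
        return np.sort(idx)
    return np.sort(rng.choice(idx, size=k, replace=False))


def burden(
    m: CellMatrix,
    control_line: str,
    mutant_line: str,
    cfg: ThresholdConfig | None = None,
    seed: int = 0,
) -> BurdenResult:
    """Iterated downsampled DEG burden of a mutant line per cluster.

    Requires a prepared matrix (QC-filtered, normalized). One master seed
    spawns an independent RNG stream per iteration, so any iteration is
    reproducible on its own and the whole result is bitwise deterministic.
    """
    cfg = cfg or ThresholdConfig()
    meta = m.cell_meta
    for line in (control_line, mutant_line):
        if not (meta["line_id"] == line).any():
            raise ValidationError(f"line {line!r} absent from matrix")
    clusters, k = eligible_clusters(m, cfg)
    samples_by_line = {
        line: sorted(meta.loc[meta["line_id"] == line, "sample_id"].unique())
        for line in (control_line, mutant_line)
    }
    streams = np.random.SeedSequence(seed).spawn(cfg.burden_iters)
    iteration_counts: dict[str, list[int]] = {c: [] for c in clusters}
    for ss in streams:
        rng = np.random.Generator(np.random.PCG64(ss))
        for cluster in clusters:
            pooled = {}
            for line in (mutant_line, control_line):
                cells = [
                    downsample(m, cluster, s, k, rng)
                    for s in samples_by_line[line]
                ]
                pooled[line] = np.concatenate(cells)
            res = run_de(
                m,
                pooled[mutant_line],
                pooled[control_line],
                cfg,
                model_id=f"{mutant_line}|{cluster}",
            )
            iteration_counts[cluster].append(res.deg_count(cfg))
    return BurdenResult(
        mutant_line=mutant_line,
        control_line=control_line,
        iteration_counts=iteration_counts,
        k_used=k,
        eligible_clusters=clusters,
        seed=seed,
    )


def composition(
    m: CellMatrix,
    control_line: str,
    line: str,
    cfg: ThresholdConfig | None = None,
) -> CompositionResult:
    """Cluster-proportion shifts of one line relative to the control.

    Per-sample proportions (each sample's proportions sum to 1) feed the
    mean +/- SEM reporting; the p-value per cluster is a two-sided Fisher
    exact test on pooled in/out-of-cluster counts for line vs control. A
    cluster absent from one line contributes zero counts and the test is
    still valid.
    """
    cfg = cfg or ThresholdConfig()
    meta = m.cell_meta
    for ln in (control_line, line):
        if not (meta["line_id"] == ln).any():
            raise ValidationError(f"line {ln!r} absent from matrix")
    sub = meta[meta["line_id"].isin([control_line, line])]
    clusters = sorted(meta["cluster_label"].unique())

    counts = pd.crosstab(sub["sample_id"], sub["cluster_label"]).reindex(
        columns=clusters, fill_value=0
    )
    props = counts.div(counts.sum(axis=1), axis=0)
    sample_line = sub.drop_duplicates("sample_id").set_index("sample_id")["line_id"]
    props.insert(0, "line_id", sample_line.reindex(props.index))

    pooled = {
        ln: sub.loc[sub["line_id"] == ln, "cluster_label"].value_counts()
        for ln in (line, control_line)
    }
    totals = {ln: int(pooled[ln].sum()) for ln in pooled}
    rows = []
    for cluster in clusters:
        in_line = int(pooled[line].get(cluster, 0))
        in_ctrl = int(pooled[control_line].get(cluster, 0))
        out_line = totals[line] - in_line
        out_ctrl = totals[control_line] - in_ctrl
        _, p = stats.fisher_exact(
            [[in_line, out_line], [in_ctrl, out_ctrl]], alternative="two-sided"
        )
        prop_line = in_line / totals[line] if totals[line] else 0.0
        prop_ctrl = in_ctrl / totals[control_line] if totals[control_line] else 0.0
        diff = prop_line - prop_ctrl
        direction = "increased" if diff > 0 else "depleted" if diff < 0 else "unchanged"
        line_props = props.loc[props["line_id"] == line, cluster]
        ctrl_props = props.loc[props["line_id"] == control_line, cluster]
        rows.append(
            {
                "cluster": cluster,
                "in_line": in_line,
                "out_line": out_line,
                "in_control": in_ctrl,
                "out_control": out_ctrl,
                "prop_line_pooled": prop_line,
                "prop_control_pooled": prop_ctrl,
                "mean_prop_line": float(line_props.mean()),
                "sem_prop_line": float(line_props.sem(ddof=1)) if len(line_props) > 1 else 0.0,
                "mean_prop_control": float(ctrl_props.mean()),
                "sem_prop_control": float(ctrl_props.sem(ddof=1)) if len(ctrl_props) > 1 else 0.0,
                "fisher_p": float(p),
                "direction": direction,
            }
        )
    return CompositionResult(
        line=line,
        control_line=control_line,
        per_cluster=pd.DataFrame(rows),
        per_sample=props,
    )
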