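"""End-to-end orchestration: simulate -> call DEGs -> concordance -> burden.

The report is a plain JSON-serializable dict, versioned and embedding every
seed and threshold used, so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np

from . import concordance as cc
from . import deg_calling as dc
from .burden_composition import burden, composition, eligible_clusters
from .sc_prep import prepare
from .synthetic import BulkSimConfig, ScSimConfig, simulate_bulk_pair, simulate_sc
from .tables_io import (
    ThresholdConfig,
    write_counts,
    write_de_table,
    write_ortholog_map,
)

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

DEFAULT_SWEEP: list[cc.Threshold] = [None, ("fdr", 0.5), ("fdr", 0.05)]


def default_run_config(seed: int = 0) -> dict[str, Any]:
    """The packaged default simulation + analysis configuration."""
    return {
        "seed": seed,
        "thresholds": {},
        "bulk_sim": {},  # BulkSimConfig defaults: planted concordant + discordant genes
        "sc_sim": {
            "cells_per_cluster_sample": [30, 45],
            "planted_degs": {"npc": 30, "nsc": 10, "neuron": 10, "gaba": 10},
            "composition": {
                "MUT1": {"npc": 0.16, "nsc": 0.28, "neuron": 0.28, "gaba": 0.28}
            },
        },
        "sweep": ["none", "fdr:0.5", "fdr:0.05"],
    }


def parse_sweep(items) -> list[cc.Threshold]:
    """Parse sweep entries like ``none``, ``fdr:0.05`` or ``raw:0.05``."""
    out: list[cc.Threshold] = []
    for item in items:
        if item is None or item == "none":
            out.append(None)
        else:
            kind, alpha = str(item).split(":")
            out.append((kind, float(alpha)))
    return out


def _gme_payload(res: cc.GmeResult) -> dict[str, Any]:
    q = res.quadrant
    return {
        "fold": None if np.isnan(res.fold) else round(res.fold, 6),
        "pvalue": res.pvalue,
        "odds_ratio": None if np.isnan(res.odds_ratio) else round(res.odds_ratio, 6),
        "n11": q.n11,
        "n10": q.n10,
        "n01": q.n01,
        "n00": q.n00,
        "U": q.U,
    }


def _fit_payload(fit: cc.FitResult) -> dict[str, Any]:
    def num(x):
        return None if not np.isfinite(x) else round(float(x), 6)

    return {
        "threshold": fit.threshold_label,
        "slope": num(fit.slope),
        "intercept": num(fit.intercept),
        "r2": num(fit.r2),
        "n_genes": fit.n_genes,
    }


def analyze_pair(
    table_a,
    table_b,
    omap,
    cfg: ThresholdConfig,
    sweep: list[cc.Threshold] | None = None,
) -> dict[str, Any]:
    """DEG calling, quadrant GME, regression sweep and sign consistency
    for one model pair joined on orthologs."""
    sweep = DEFAULT_SWEEP if sweep is None else sweep
    joined = cc.join_on_orthologs(table_a, table_b, omap)

    degs = {}
    for table in (table_a, table_b):
        degs[table.model_id] = {
            d: dc.extract_degs(table, d, cfg) for d in ("up", "down")
        }
    up_a, down_a = degs[table_a.model_id]["up"], degs[table_a.model_id]["down"]
    up_b_raw, down_b_raw = degs[table_b.model_id]["up"], degs[table_b.model_id]["down"]
    up_b = dataclasses.replace(up_b_raw, genes=joined.map_b_genes(up_b_raw.genes))
    down_b = dataclasses.replace(down_b_raw, genes=joined.map_b_genes(down_b_raw.genes))

    gme_results = cc.gme_all_quadrants(up_a, down_a, up_b, down_b, joined.universe)

    x_genes = (up_a.genes | down_a.genes) & joined.universe
    fits = cc.threshold_sweep(joined, x_genes, sweep)

    # Discordant genes: opposite-direction overlaps; their queried direction
    # in model B is model B's own observed direction (sign test asks whether
    # the raw fold changes in B really go that way).
    b_dirs: dict[str, str] = {}
    a_to_b = {a: b for b, a in joined.b_to_a.items()}
    for g in gme_results["up-down"].genes_overlap:
        b_dirs[a_to_b[g]] = "down"
    for g in gme_results["down-up"].genes_overlap:
        b_dirs[a_to_b[g]] = "up"
    sign = cc.sign_consistency(b_dirs, table_b)

    return {
        "models": [table_a.model_id, table_b.model_id],
        "joint_universe": len(joined.universe),
        "deg_counts": {
            t.model_id: {
                "up": len(degs[t.model_id]["up"]),
                "down": len(degs[t.model_id]["down"]),
                "p_mode": dc.effective_p_mode(t, cfg),
            }
            for t in (table_a, table_b)
        },
        "gme": {label: _gme_payload(res) for label, res in gme_results.items()},
        "sweep": [_fit_payload(f) for f in fits],
        "sign_consistency": {
            "n_agree": sign.n_agree,
            "n_total": sign.n_total,
            "p_binomial": sign.p_binomial,
        },
        "_joined": joined,
        "_gme_results": gme_results,
    }


def run_full(config: Mapping[str, Any], out_dir: str | Path | None = None) -> dict[str, Any]:
    """Execute the full synthetic pipeline described by ``config``.

    Returns the report dict; when ``out_dir`` is given, also writes
    report.json plus the generated tables/matrices and per-stage TSVs.
    """
    seed = int(config.get("seed", 0))
    cfg = ThresholdConfig(**config.get("thresholds", {}))
    sweep = parse_sweep(config.get("sweep", ["none", "fdr:0.5", "fdr:0.05"]))
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    logger.info("run_full: seed=%d", seed)
    bulk_kwargs = dict(config.get("bulk_sim", {}))
    bulk_kwargs.setdefault("seed", seed)
    bulk_cfg = BulkSimConfig(**bulk_kwargs)
    table_a, table_b, omap, bulk_truth = simulate_bulk_pair(bulk_cfg)

    pair_report = analyze_pair(table_a, table_b, omap, cfg, sweep)
    joined = pair_report.pop("_joined")
    pair_report.pop("_gme_results")

    sc_kwargs = dict(config.get("sc_sim", {}))
    sc_kwargs.setdefault("seed", seed + 1)
    if "cells_per_cluster_sample" in sc_kwargs:
        sc_kwargs["cells_per_cluster_sample"] = tuple(
            sc_kwargs["cells_per_cluster_sample"]
        )
    sc_cfg = ScSimConfig(**sc_kwargs)
    matrix, sc_truth = simulate_sc(sc_cfg)
    prepared = prepare(matrix, cfg)
    clusters, k = eligible_clusters(prepared, cfg)

    sc_report: dict[str, Any] = {
        "eligible_clusters": clusters,
        "k": k,
        "burden": {},
        "composition": {},
    }
    burdens = {}
    for line in sc_cfg.mutant_lines:
        b = burden(prepared, sc_cfg.control_line, line, cfg, seed=seed + 2)
        burdens[line] = b
        sc_report["burden"][line] = {
            "mean_counts": {c: round(v, 4) for c, v in b.mean_counts.items()},
            "k": b.k_used,
            "iterations": cfg.burden_iters,
            "seed": b.seed,
        }
        comp = composition(prepared, sc_cfg.control_line, line, cfg)
        sc_report["composition"][line] = [
            {
                "cluster": row["cluster"],
                "prop_line": round(row["prop_line_pooled"], 6),
                "prop_control": round(row["prop_control_pooled"], 6),
                "fisher_p": row["fisher_p"],
                "direction": row["direction"],
            }
            for _, row in comp.per_cluster.iterrows()
        ]

    report = {
        "schema_version": SCHEMA_VERSION,
        "seed": seed,
        "thresholds": dataclasses.asdict(cfg),
        "bulk": pair_report,
        "sc": sc_report,
    }

    if out is not None:
        write_de_table(table_a, out / "table_a.tsv", out / "universe_a.txt")
        write_de_table(table_b, out / "table_b.tsv", out / "universe_b.txt")
        write_ortholog_map(omap, out / "ortholog_map.tsv")
        bulk_truth.genes.to_csv(out / "bulk_truth.tsv", sep="\t", index=False)
        write_counts(
            matrix, out / "counts.mtx", out / "genes.tsv", out / "cells.tsv"
        )
        joined.df.to_csv(out / "joined_records.tsv", sep="\t")
        for line, b in burdens.items():
            b.to_frame().to_csv(out / f"burden_{line}.tsv", sep="\t", index=False)
        (out / "report.json").write_text(
            json.dumps(report, sort_keys=True, indent=2) + "\n"
        )
    return report
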