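"""Shared fixtures: hand-built tables and matrices with enumerable truth."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import HealthCheck, settings

from dyscord import CellMatrix, DeTable, ThresholdConfig

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def make_de_table(rows, universe=None, model_id="toy", species="") -> DeTable:
    """rows: list of (gene, log2fc, pvalue, fdr)."""
    df = pd.DataFrame(rows, columns=["gene", "log2fc", "pvalue", "fdr"])
    return DeTable(
        model_id=model_id,
        species=species,
        df=df,
        universe=frozenset(universe) if universe is not None else frozenset(df["gene"]),
    )


@pytest.fixture
def cfg() -> ThresholdConfig:
    return ThresholdConfig()


@pytest.fixture
def six_gene_table() -> DeTable:
    """Hand-checked DEG truth at lfc>0.25, fdr<0.05 (fdr mode forced off by
    count): up = {u1}, down = {d1} in raw mode at p<0.05; boundary genes
    excluded."""
    return make_de_table(
        [
            ("u1", 0.80, 0.001, 0.006),   # clear up
            ("u2", 0.25, 0.001, 0.006),   # boundary lfc: excluded
            ("d1", -0.90, 0.002, 0.006),  # clear down
            ("d2", -0.20, 0.001, 0.006),  # |lfc| below threshold
            ("n1", 0.60, 0.200, 0.300),   # not significant
            ("n2", 0.00, 0.900, 0.950),   # null
        ]
    )


def qc_toy_config() -> ThresholdConfig:
    """Thresholds scaled to the 50x30 QC fixture."""
    return ThresholdConfig(
        qc_min_cells_per_gene=3,
        qc_min_genes_per_cell=20,
        qc_max_genes_per_cell=40,
        qc_max_mito_frac=0.10,
    )


def make_qc_fixture() -> CellMatrix:
    """Deterministic 50 genes x 30 cells matrix with exactly 6 failing genes
    and 6 failing cells under :func:`qc_toy_config`.

    Genes 0..43 survive (ids G00..G41 plus MT-1, MT-2 at rows 42/43); genes
    44..49 are expressed in only 2 cells. Cells 0..23 survive (36 expressed
    genes, mito fraction 2/36); cells 24,25 express 10 genes (too few),
    cells 26,27 express all 50 (too many after gene filtering: 44 > 40),
    cells 28,29 express 32 genes but carry 10 counts per mito gene
    (fraction 20/50 > 0.10), so they fail the mito rule alone.
    """
    X = np.zeros((50, 30), dtype=np.int64)
    for c in range(12):  # good cells, first half of the gene span
        X[0:34, c] = 1
        X[42:44, c] = 1  # mito genes, fraction 2/36
    for c in range(12, 24):  # good cells, second half of the gene span
        X[8:42, c] = 1
        X[42:44, c] = 1
    for c in (24, 25):  # too few genes
        X[0:10, c] = 1
    for c in (26, 27):  # too many genes; only cells expressing genes 44..49
        X[:, c] = 1
    for c in (28, 29):  # high mito, gene count within range
        X[0:30, c] = 1
        X[42:44, c] = 10
    gene_ids = [f"G{i:02d}" for i in range(42)] + ["MT-1", "MT-2"] + [
        f"BAD{i}" for i in range(6)
    ]
    meta = pd.DataFrame(
        {
            "cell_id": [f"c{i:02d}" for i in range(30)],
            "sample_id": ["s1"] * 15 + ["s2"] * 15,
            "line_id": ["CTRL"] * 30,
            "cluster_label": ["clu"] * 30,
        }
    )
    return CellMatrix(counts=sp.csr_matrix(X), gene_ids=pd.Index(gene_ids), cell_meta=meta)


@pytest.fixture
def qc_fixture() -> CellMatrix:
    return make_qc_fixture()
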