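"""Synthetic inputs with recorded planted truth.

Two generators cover everything the pipeline consumes:

* :func:`simulate_bulk_pair` emits a pair of gene-level DE tables under a
  shared-signal model: each gene is concordant (same true log2 effect in
  both models), discordant (opposite signs) or null; observed log2
  fold changes add independent per-model Gaussian noise with known standard
  error, so p-values have a closed form and calibration properties are
  analytic. Human-style (UPPER) and mouse-style (Title) symbols exercise
  the ortholog-mapping path.
* :func:`simulate_sc` emits a multi-line, multi-sample annotated count
  matrix with negative-binomial counts, cluster structure, per-line
  composition shifts and cluster-specific planted DEGs, including
  mitochondrial-prefixed genes so QC is exercised.

Neither generator imitates any real dataset's library sizes or gene panel;
they reproduce the statistical structure the analyses assume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .de_engine import bh_adjust
from .errors import ValidationError
from .tables_io import CellMatrix, DeTable, OrthologMap

GENE_CLASSES = ("concordant-up", "concordant-down", "discordant", "null")


@dataclass
class PlantedTruth:
    """Ground truth recorded alongside generated data."""

    genes: pd.DataFrame | None = None  # human, mouse, klass, theta_a, theta_b
    sc_deg_sets: dict[tuple[str, str], frozenset[str]] = field(default_factory=dict)
    sc_composition: dict[str, dict[str, float]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Bulk DE-table pair
# ---------------------------------------------------------------------------

@dataclass
class BulkSimConfig:
    """Shared-signal + independent-noise model for a pair of DE tables.

    ``f_conc``/``f_disc`` fractions of genes carry a planted effect whose
    magnitude is |Normal(effect_mu, effect_sd)| with a random sign, shared
    across models (same sign for concordant, opposite for discordant
    genes). Observed log2fc adds Normal(0, se) noise per model; p-values
    are the corresponding two-sided normal tails, FDR is BH per table.
    """

    G: int = 5000
    f_conc: float = 0.10
    f_disc: float = 0.05
    effect_mu: float = 1.5
    effect_sd: float = 0.4
    se_a: float = 0.3
    se_b: float = 0.3
    universe_dropout: float = 0.02
    ortholog_dropout: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.G <= 0:
            raise ValidationError("G must be positive")
        if not (0 <= self.f_conc <= 1 and 0 <= self.f_disc <= 1):
            raise ValidationError("class fractions must be in [0, 1]")
        if self.f_conc + self.f_disc > 1:
            raise ValidationError("f_conc + f_disc must not exceed 1")
        for name, val in (("effect_sd", self.effect_sd), ("se_a", self.se_a), ("se_b", self.se_b)):
            if not val > 0:
                raise ValidationError(f"{name} must be positive")
        for name, val in (
            ("universe_dropout", self.universe_dropout),
            ("ortholog_dropout", self.ortholog_dropout),
        ):
            if not 0 <= val < 1:
                raise ValidationError(f"{name} must be in [0, 1)")


def population_r2(cfg: BulkSimConfig) -> float:
    """Analytic squared correlation of the two emitted log2fc vectors.

    With sign-symmetric effects, Var(theta) = f_tot * (mu^2 + sd^2) per
    model and Cov = (f_conc - f_disc) * (mu^2 + sd^2), so
    r^2 = Cov^2 / ((Var_theta + se_a^2)(Var_theta + se_b^2)).
    """
    m2 = cfg.effect_mu**2 + cfg.effect_sd**2
    f_tot = cfg.f_conc + cfg.f_disc
    cov = (cfg.f_conc - cfg.f_disc) * m2
    var_a = f_tot * m2 + cfg.se_a**2
    var_b = f_tot * m2 + cfg.se_b**2
    return float(cov**2 / (var_a * var_b))


def simulate_bulk_pair(
    cfg: BulkSimConfig,
) -> tuple[DeTable, DeTable, OrthologMap, PlantedTruth]:
    """Generate a human-style/mouse-style DE table pair with planted truth."""
    rng = np.random.default_rng(cfg.seed)
    G = cfg.G
    human = np.array([f"GENE{i:05d}" for i in range(G)], dtype=object)
    mouse = np.array([f"Gene{i:05d}" for i in range(G)], dtype=object)

    n_conc = round(cfg.f_conc * G)
    n_disc = round(cfg.f_disc * G)
    order = rng.permutation(G)
    conc_idx = order[:n_conc]
    disc_idx = order[n_conc : n_conc + n_disc]

    theta_a = np.zeros(G)
    theta_b = np.zeros(G)
    klass = np.full(G, "null", dtype=object)
    signs = rng.choice([-1.0, 1.0], size=G)
    magnitude = np.abs(rng.normal(cfg.effect_mu, cfg.effect_sd, size=G))
    theta_a[conc_idx] = signs[conc_idx] * magnitude[conc_idx]
    theta_b[conc_idx] = theta_a[conc_idx]
    klass[conc_idx] = np.where(signs[conc_idx] > 0, "concordant-up", "concordant-down")
    theta_a[disc_idx] = signs[disc_idx] * magnitude[disc_idx]
    theta_b[disc_idx] = -theta_a[disc_idx]
    klass[disc_idx] = "discordant"

    def make_table(gene_ids, theta, se, model_id, species):
        lfc = theta + rng.normal(0.0, se, size=G)
        pval = 2.0 * stats.norm.sf(np.abs(lfc) / se)
        keep = rng.random(G) >= cfg.universe_dropout
        df = pd.DataFrame(
            {
                "gene": gene_ids[keep],
                "log2fc": lfc[keep],
                "pvalue": pval[keep],
                "fdr": bh_adjust(pval[keep]),
            }
        )
        return DeTable(
            model_id=model_id,
            species=species,
            df=df,
            universe=frozenset(gene_ids[keep]),
        )

    table_a = make_table(human, theta_a, cfg.se_a, "model_a", "human")
    table_b = make_table(mouse, theta_b, cfg.se_b, "model_b", "mouse")

    keep_pair = rng.random(G) >= cfg.ortholog_dropout
    omap = OrthologMap(
        tuple((h, m) for h, m, k in zip(human, mouse, keep_pair) if k)
    )
    truth = PlantedTruth(
        genes=pd.DataFrame(
            {
                "human": human,
                "mouse": mouse,
                "klass": klass,
                "theta_a": theta_a,
                "theta_b": theta_b,
            }
        )
    )
    return table_a, table_b, omap, truth


# ---------------------------------------------------------------------------
# Single-cell counts
# ---------------------------------------------------------------------------

@dataclass
class ScSimConfig:
    """Multi-line, multi-sample negative-binomial single-cell simulation.

    Counts for gene g in a cell of cluster c are NB with mean
    size_factor * base_mean[g] * marker_boost[g, c] * 2^deg_lfc (the last
    factor only for planted DEGs of the cell's cluster in mutant lines) and
    a single shared dispersion (variance = mu + dispersion * mu^2).
    Composition gives each line's expected cluster proportions; per-sample
    cell numbers vary uniformly in ``cells_per_cluster_sample``. The study
    design this emulates is 3 lines x 5 replicate samples.
    """

    n_genes: int = 800
    n_mito: int = 5
    clusters: Sequence[str] = ("npc", "nsc", "neuron", "gaba")
    control_line: str = "CTRL"
    mutant_lines: Sequence[str] = ("MUT1",)
    samples_per_line: int = 5
    cells_per_cluster_sample: tuple[int, int] = (50, 80)
    nb_dispersion: float = 0.5
    base_mean_log_mu: float = float(np.log(0.8))
    base_mean_log_sd: float = 1.0
    n_markers_per_cluster: int = 15
    marker_boost: float = 3.0
    composition: Mapping[str, Mapping[str, float]] | None = None
    planted_degs: Mapping[str, int] = field(default_factory=dict)
    deg_lfc: float = 1.0
    mito_frac: float = 0.05
    size_factor_log_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= self.n_mito:
            raise ValidationError("n_genes must exceed n_mito")
        lo, hi = self.cells_per_cluster_sample
        if not 0 < lo <= hi:
            raise ValidationError("cells_per_cluster_sample must be a positive range")
        if self.nb_dispersion <= 0:
            raise ValidationError("nb_dispersion must be positive")
        if not 0 < self.mito_frac < 1:
            raise ValidationError("mito_frac must be in (0, 1)")
        if self.composition is not None:
            for line, weights in self.composition.items():
                total = sum(weights.get(c, 0.0) for c in self.clusters)
                if abs(total - 1.0) > 1e-8:
                    raise ValidationError(
                        f"composition for line {line!r} sums to {total}, not 1"
                    )
        unknown = set(self.planted_degs) - set(self.clusters)
        if unknown:
            raise ValidationError(f"planted_degs for unknown cluster(s): {unknown}")

    @property
    def lines(self) -> list[str]:
        return [self.control_line, *self.mutant_lines]


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with var = mu + dispersion * mu^2."""
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_sc(cfg: ScSimConfig) -> tuple[CellMatrix, PlantedTruth]:
    """Generate an annotated count matrix and its planted truth."""
    rng = np.random.default_rng(cfg.seed)
    n_real = cfg.n_genes - cfg.n_mito
    gene_ids = np.array(
        [f"G{i:04d}" for i in range(n_real)]
        + [f"MT-{i + 1}" for i in range(cfg.n_mito)],
        dtype=object,
    )
    base = np.empty(cfg.n_genes)
    base[:n_real] = rng.lognormal(cfg.base_mean_log_mu, cfg.base_mean_log_sd, n_real)
    mito_total = cfg.mito_frac / (1.0 - cfg.mito_frac) * base[:n_real].sum()
    base[n_real:] = mito_total / cfg.n_mito

    # Cluster-specific multipliers: markers make clusters distinguishable;
    # planted DEGs get a 2^deg_lfc boost in mutant lines only.
    cluster_mult = {c: np.ones(cfg.n_genes) for c in cfg.clusters}
    available = list(rng.permutation(n_real))
    planted: dict[str, np.ndarray] = {}
    for c in cfg.clusters:
        n_deg = int(cfg.planted_degs.get(c, 0))
        planted[c] = np.array(sorted(available[:n_deg]), dtype=int)
        available = available[n_deg:]
    for c in cfg.clusters:
        markers = rng.choice(available, size=min(cfg.n_markers_per_cluster, len(available)), replace=False)
        cluster_mult[c][markers] = cfg.marker_boost

    comp = {
        line: (
            {c: 1.0 / len(cfg.clusters) for c in cfg.clusters}
            if cfg.composition is None or line not in cfg.composition
            else {c: float(cfg.composition[line].get(c, 0.0)) for c in cfg.clusters}
        )
        for line in cfg.lines
    }

    lo, hi = cfg.cells_per_cluster_sample
    blocks = []
    meta_rows = []
    cell_counter = 0
    for line in cfg.lines:
        is_mutant = line != cfg.control_line
        for s in range(cfg.samples_per_line):
            sample_id = f"{line}_s{s + 1}"
            total = int(rng.integers(lo, hi + 1)) * len(cfg.clusters)
            for c in cfg.clusters:
                n_cells = max(1, round(total * comp[line][c]))
                mean_g = base * cluster_mult[c]
                if is_mutant and planted[c].size:
                    mean_g = mean_g.copy()
                    mean_g[planted[c]] *= 2.0**cfg.deg_lfc
                size_factors = rng.lognormal(0.0, cfg.size_factor_log_sd, n_cells)
                mu = mean_g[:, None] * size_factors[None, :]
                block = _nb_draw(rng, mu, cfg.nb_dispersion)
                blocks.append(sp.csr_matrix(block))
                for _ in range(n_cells):
                    meta_rows.append(
                        {
                            "cell_id": f"cell{cell_counter:06d}",
                            "sample_id": sample_id,
                            "line_id": line,
                            "cluster_label": c,
                        }
                    )
                    cell_counter += 1
    counts = sp.hstack(blocks, format="csr")
    matrix = CellMatrix(
        counts=counts,
        gene_ids=pd.Index(gene_ids),
        cell_meta=pd.DataFrame(meta_rows),
    )
    truth = PlantedTruth(
        sc_deg_sets={
            (c, line): frozenset(gene_ids[planted[c]])
            for c in cfg.clusters
            for line in cfg.mutant_lines
        },
        sc_composition=comp,
    )
    return matrix, truth
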