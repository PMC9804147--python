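"""Quadrant counting, GME Fisher oracle, regression, sign consistency."""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dyscord import (
    OrthologMap,
    QuadrantTable,
    ThresholdConfig,
    ValidationError,
    extract_degs,
    gme,
    gme_all_quadrants,
    join_on_orthologs,
    lfc_regression,
    quadrant_counts,
    sign_consistency,
    threshold_sweep,
)
from dyscord.synthetic import BulkSimConfig, simulate_bulk_pair

from conftest import make_de_table


def hypergeom_upper_tail(n11: int, n10: int, n01: int, n00: int) -> float:
    """Exact P(X >= n11), X ~ Hypergeom(N=U, K=|A|, n=|B|), by enumeration."""
    U = n11 + n10 + n01 + n00
    a = n11 + n10
    b = n11 + n01
    total = Fraction(0)
    for k in range(n11, min(a, b) + 1):
        total += Fraction(math.comb(a, k) * math.comb(U - a, b - k), math.comb(U, b))
    return float(total)


class TestJoin:
    def make_pair(self):
        a = make_de_table(
            [(f"H{i}", 0.1 * i, 0.5, 0.6) for i in range(20)],
            model_id="A",
        )
        b = make_de_table(
            [(f"m{i}", -0.1 * i, 0.5, 0.6) for i in range(20)],
            model_id="B",
        )
        return a, b

    def test_identity_map_universe_is_intersection(self):
        a, b = self.make_pair()
        omap = OrthologMap(tuple((f"H{i}", f"m{i}") for i in range(20)))
        joined = join_on_orthologs(a, b, omap)
        assert joined.universe == a.universe
        assert len(joined.df) == 20

    def test_dropped_orthologs_shrink_universe(self):
        # 3 of 20 pairs removed from the map -> 17-gene joint universe
        a, b = self.make_pair()
        omap = OrthologMap(tuple((f"H{i}", f"m{i}") for i in range(20) if i > 2))
        joined = join_on_orthologs(a, b, omap)
        assert len(joined.universe) == 17
        assert joined.universe == {f"H{i}" for i in range(3, 20)}

    def test_pair_absent_from_universe_excluded(self):
        a, b = self.make_pair()
        omap = OrthologMap((("H0", "m0"), ("H1", "mMISSING")))
        joined = join_on_orthologs(a, b, omap)
        assert joined.universe == {"H0"}

    def test_empty_joint_universe_is_error(self):
        a, b = self.make_pair()
        omap = OrthologMap((("HX", "mX"),))
        with pytest.raises(ValidationError, match="universe"):
            join_on_orthologs(a, b, omap)

    def test_joined_records_carry_both_models(self):
        a, b = self.make_pair()
        omap = OrthologMap(tuple((f"H{i}", f"m{i}") for i in range(20)))
        joined = join_on_orthologs(a, b, omap)
        row = joined.df.loc["H5"]
        assert row["log2fc_a"] == pytest.approx(0.5)
        assert row["log2fc_b"] == pytest.approx(-0.5)


class TestQuadrants:
    def test_disjoint_sets(self):
        u = {f"g{i}" for i in range(20)}
        a = {f"g{i}" for i in range(5)}
        b = {f"g{i}" for i in range(5, 13)}
        q = quadrant_counts(a, b, u)
        assert (q.n11, q.n10, q.n01, q.n00) == (0, 5, 8, 7)

    def test_full_overlap(self):
        u = {f"g{i}" for i in range(9)}
        q = quadrant_counts(u, u, u)
        assert (q.n11, q.n10, q.n01, q.n00) == (9, 0, 0, 0)

    def test_partial_overlap_enumerated(self):
        u = {f"g{i}" for i in range(20)}
        a = {f"g{i}" for i in range(5)}          # g0..g4
        b = {f"g{i}" for i in range(1, 5)} | {"g10", "g11", "g12", "g13"}
        q = quadrant_counts(a, b, u)
        assert (q.n11, q.n10, q.n01, q.n00) == (4, 1, 4, 11)

    def test_sets_clipped_to_universe(self):
        u = {"g0", "g1"}
        q = quadrant_counts({"g0", "zz"}, {"g0", "yy"}, u)
        assert (q.n11, q.n10, q.n01, q.n00) == (1, 0, 0, 1)


class TestGme:
    def test_enumerated_tail_and_fold(self):
        res = gme(QuadrantTable(4, 1, 4, 11))
        assert res.fold == pytest.approx(4 * 20 / (5 * 8))  # = 2.0
        assert res.pvalue == pytest.approx(hypergeom_upper_tail(4, 1, 4, 11), abs=1e-12)

    def test_zero_overlap_minimum_tail(self):
        res = gme(QuadrantTable(0, 5, 8, 7))
        assert res.fold == 0.0
        assert res.pvalue == 1.0

    def test_empty_marginal_undefined(self):
        res = gme(QuadrantTable(0, 0, 8, 12))
        assert math.isnan(res.fold)
        assert res.pvalue == 1.0

    def test_transpose_symmetry(self):
        q = QuadrantTable(7, 3, 9, 41)
        qt = QuadrantTable(7, 9, 3, 41)
        a, b = gme(q), gme(qt)
        assert a.fold == pytest.approx(b.fold)
        assert a.pvalue == pytest.approx(b.pvalue)

    def test_fold_one_at_expected_overlap(self):
        # |A| = 10, |B| = 20, U = 100 -> expected overlap 2
        q = QuadrantTable(2, 8, 18, 72)
        assert gme(q).fold == pytest.approx(1.0)

    def test_fold_is_geometric_mean_of_conditional_enrichments(self):
        q = QuadrantTable(6, 4, 14, 76)
        a, b, U = q.n11 + q.n10, q.n11 + q.n01, q.U
        e1 = (q.n11 / a) / (b / U)
        e2 = (q.n11 / b) / (a / U)
        assert gme(q).fold == pytest.approx(math.sqrt(e1 * e2), abs=1e-12)

    def test_all_empty_sets_give_four_undefined_folds(self, cfg):
        empty = make_de_table([("g0", 0.0, 1.0, 1.0)] +
                              [(f"f{i}", 1.0, 1e-4, 0.01) for i in range(11)])
        up = extract_degs(empty, "up", cfg)
        down = extract_degs(empty, "down", cfg)
        none_up = up.__class__("up", frozenset(), "x", "fdr", 0.25, 0.05)
        none_down = up.__class__("down", frozenset(), "x", "fdr", 0.25, 0.05)
        res = gme_all_quadrants(none_up, none_down, none_up, none_down, {"g0"})
        assert all(math.isnan(r.fold) and r.pvalue == 1.0 for r in res.values())


@given(
    st.tuples(
        st.integers(0, 12), st.integers(0, 12), st.integers(0, 12), st.integers(0, 12)
    )
)
def test_gme_matches_enumeration_oracle(counts):
    """One-sided Fisher p equals the exact hypergeometric upper tail."""
    n11, n10, n01, n00 = counts
    res = gme(QuadrantTable(n11, n10, n01, n00))
    if (n11 + n10) == 0 or (n11 + n01) == 0:
        assert res.pvalue == 1.0
    else:
        assert res.pvalue == pytest.approx(
            hypergeom_upper_tail(n11, n10, n01, n00), abs=1e-10
        )


class TestRegression:
    @staticmethod
    def joined_from_points(points):
        a = make_de_table(
            [(f"g{i}", x, 0.5, 0.6) for i, (x, _) in enumerate(points)], model_id="A"
        )
        b = make_de_table(
            [(f"h{i}", y, 0.5, 0.6) for i, (_, y) in enumerate(points)], model_id="B"
        )
        omap = OrthologMap(tuple((f"g{i}", f"h{i}") for i in range(len(points))))
        return join_on_orthologs(a, b, omap)

    def test_perfect_line(self):
        joined = self.joined_from_points([(0, 0), (1, 1), (2, 2)])
        fit = lfc_regression(joined, joined.universe)
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_hand_least_squares(self):
        # Sxy = 1, Sxx = 5, Syy = 1 -> slope .2, intercept .2, r2 = .2
        joined = self.joined_from_points([(0, 0), (1, 1), (2, 0), (3, 1)])
        fit = lfc_regression(joined, joined.universe)
        assert fit.slope == pytest.approx(0.2)
        assert fit.intercept == pytest.approx(0.2)
        assert fit.r2 == pytest.approx(0.2)

    def test_r2_equals_squared_pearson(self):
        rng = np.random.default_rng(42)
        pts = list(zip(rng.normal(size=50), rng.normal(size=50)))
        joined = self.joined_from_points(pts)
        fit = lfc_regression(joined, joined.universe)
        r = np.corrcoef([p[0] for p in pts], [p[1] for p in pts])[0, 1]
        assert fit.r2 == pytest.approx(r**2, abs=1e-10)

    def test_underdetermined_fit_flagged(self):
        joined = self.joined_from_points([(0, 0), (1, 1), (2, 2)])
        fit = lfc_regression(joined, {"g0", "g1"})
        assert not fit.defined
        assert fit.n_genes == 2

    def test_sweep_counts_non_increasing_and_first_equals_plain(self):
        cfgb = BulkSimConfig(G=800, f_conc=0.2, f_disc=0.0, seed=7)
        ta, tb, omap, _ = simulate_bulk_pair(cfgb)
        joined = join_on_orthologs(ta, tb, omap)
        cfg = ThresholdConfig()
        x = (
            extract_degs(ta, "up", cfg).genes | extract_degs(ta, "down", cfg).genes
        ) & joined.universe
        fits = threshold_sweep(joined, x, [None, ("fdr", 0.5), ("fdr", 0.05)])
        ns = [f.n_genes for f in fits]
        assert ns == sorted(ns, reverse=True)
        plain = lfc_regression(joined, x, None)
        assert fits[0].r2 == pytest.approx(plain.r2)
        assert fits[0].threshold_label == "none"


class TestSignConsistency:
    def test_unanimous(self):
        target = make_de_table([(f"g{i}", 0.5, 0.1, 0.2) for i in range(5)])
        res = sign_consistency({f"g{i}": "up" for i in range(5)}, target)
        assert (res.n_agree, res.n_total) == (5, 5)
        assert res.p_binomial == pytest.approx(2 / 32)

    def test_four_of_five(self):
        rows = [(f"g{i}", 0.5, 0.1, 0.2) for i in range(4)] + [("g4", -0.5, 0.1, 0.2)]
        res = sign_consistency({f"g{i}": "up" for i in range(5)}, make_de_table(rows))
        assert (res.n_agree, res.n_total) == (4, 5)
        assert res.p_binomial == pytest.approx(12 / 32)  # exact enumeration of 2^5

    def test_zero_counts_as_disagreement(self):
        res = sign_consistency(
            {"g0": "up"}, make_de_table([("g0", 0.0, 0.5, 0.5)])
        )
        assert (res.n_agree, res.n_total) == (0, 1)

    def test_missing_genes_dropped(self):
        target = make_de_table([("g0", 1.0, 0.1, 0.2)])
        res = sign_consistency({"g0": "up", "absent": "up"}, target)
        assert res.n_total == 1
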