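"""Monte Carlo saturation model: estimators, closed forms, scaling."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import platepool as pp
from platepool.errors import ValidationError
from platepool.io import Contig, ContigRegistry, GeneAnnotation, InsertionTable
from platepool.mapping import AssemblyStats


@pytest.fixture(scope="module")
def one_barcode_per_gene():
    """100 equal-weight single-insertion barcodes, one per 100 genes."""
    params = pp.SimParams(seed=1, n_genes=100)
    ann, reg = pp.make_genome(params)
    rng = np.random.default_rng(0)
    rows, bcs = [], []
    for g in ann.genes.itertuples():
        bc = "".join(rng.choice(list("ACGT"), size=20))
        bcs.append(bc)
        rows.append((bc, g.contig, (g.start + g.end) // 2, "+", 100))
    table = InsertionTable(
        pd.DataFrame(rows, columns=["barcode", "contig", "position", "strand", "reads"]),
        reg,
    )
    weights = {bc: 1.0 for bc in bcs}
    return weights, table, ann


class TestEstimateK:
    def _stats(self, p1, f_single, useful):
        return AssemblyStats(
            n_wells=100,
            bpw_fractions={0: 1 - p1, 1: p1},
            f_single=f_single,
            fraction_useful_wells=useful,
        )

    def test_k_is_product_of_bpw1_and_f_single(self):
        stats = self._stats(0.7, 0.8, 0.56)
        assert pp.estimate_K(stats) == pytest.approx(0.56)

    def test_perfect_collection_has_k_one(self):
        assert pp.estimate_K(self._stats(1.0, 1.0, 1.0)) == 1.0

    def test_disagreement_with_direct_estimator_warns(self):
        stats = self._stats(0.7, 0.8, 0.40)
        with pytest.warns(UserWarning, match="direct"):
            pp.estimate_K(stats)

    def test_truth_stats_match_planted_rates(self, classify_study):
        """Direct useful-well estimate tracks the planted single fraction
        within the 99 % binomial interval."""
        from scipy import stats as sstats

        study = classify_study
        stats = study.truth_assembly_stats()
        p = study.params
        # a well is useful iff non-empty and holding a single-class strain
        weights = np.array([s.weight for s in study.pool])
        p_single_w = weights[[s.strain_class == "single" for s in study.pool]].sum()
        expect = (1 - p.empty_well_p) * p_single_w
        n = stats.n_wells
        lo, hi = sstats.binom.ppf([0.005, 0.995], n, expect) / n
        assert lo <= stats.fraction_useful_wells <= hi


class TestDraws:
    def test_zero_draws_is_empty(self):
        rng = np.random.default_rng(0)
        assert len(pp.draw_collection(np.array([1.0]), 0, rng)) == 0

    def test_degenerate_weight_draws_one_barcode(self):
        rng = np.random.default_rng(0)
        draws = pp.draw_collection(np.array([1.0]), 10, rng)
        assert (draws == 0).all()

    def test_binomial_moments(self):
        rng = np.random.default_rng(0)
        draws = pp.draw_collection(np.array([0.9, 0.1]), 10_000, rng)
        n0 = (draws == 0).sum()
        assert abs(n0 - 9000) <= 3 * np.sqrt(900)


class TestSaturationCurve:
    def test_coupon_collector_closed_form_within_monte_carlo_error(
        self, one_barcode_per_gene
    ):
        weights, table, ann = one_barcode_per_gene
        grid = (25, 50, 100, 200, 400)
        cfg = pp.SimulationConfig(seed=7, well_grid=grid, reps=250, K=1.0)
        curve = pp.saturation_curve(weights, table, ann, cfg)
        G = 100
        for i, w in enumerate(grid):
            expected = G * (1 - (1 - 1 / G) ** w)
            se = curve.coverage[:, i].std(ddof=1) / np.sqrt(cfg.reps)
            assert abs(curve.mean[i] - expected) <= 3 * max(se, 1e-9)

    def test_weighted_closed_form_oracle(self, one_barcode_per_gene):
        """sum_g (1-(1-p_g)^b) with arbitrary weights matches the Monte Carlo
        mean within 3 standard errors."""
        weights, table, ann = one_barcode_per_gene
        rng = np.random.default_rng(3)
        weights = {bc: float(w) for bc, w in
                   zip(weights, rng.lognormal(0, 1, len(weights)))}
        grid = (50, 150, 300)
        cfg = pp.SimulationConfig(seed=11, well_grid=grid, reps=250, K=1.0)
        curve = pp.saturation_curve(weights, table, ann, cfg)
        p_g = pp.gene_weight_totals(weights, table, ann)
        expected = pp.expected_coverage(p_g, np.array(grid))
        for i in range(len(grid)):
            se = curve.coverage[:, i].std(ddof=1) / np.sqrt(cfg.reps)
            assert abs(curve.mean[i] - expected[i]) <= 3 * max(se, 1e-9)

    def test_halving_K_equals_halving_collection_size(self, one_barcode_per_gene):
        weights, table, ann = one_barcode_per_gene
        half = pp.saturation_curve(
            weights, table, ann,
            pp.SimulationConfig(seed=7, well_grid=(50, 100, 200), reps=40, K=0.5),
        )
        full = pp.saturation_curve(
            weights, table, ann,
            pp.SimulationConfig(seed=7, well_grid=(25, 50, 100), reps=40, K=1.0),
        )
        assert np.array_equal(half.coverage, full.coverage)

    def test_zero_wells_give_zero_coverage(self, one_barcode_per_gene):
        weights, table, ann = one_barcode_per_gene
        cfg = pp.SimulationConfig(seed=7, well_grid=(0, 50), reps=20, K=1.0)
        curve = pp.saturation_curve(weights, table, ann, cfg)
        assert curve.mean[0] == 0.0

    def test_curves_are_monotone_and_bounded_by_pool_coverage(
        self, one_barcode_per_gene
    ):
        weights, table, ann = one_barcode_per_gene
        cfg = pp.SimulationConfig(seed=7, well_grid=(25, 50, 100, 400), reps=50)
        curve = pp.saturation_curve(weights, table, ann, cfg)
        assert (np.diff(curve.coverage, axis=1) >= 0).all()
        assert (curve.coverage <= curve.pool_covered_genes).all()

    def test_determinism_under_fixed_seed(self, one_barcode_per_gene):
        weights, table, ann = one_barcode_per_gene
        cfg = pp.SimulationConfig(seed=9, well_grid=(50, 100), reps=30)
        a = pp.saturation_curve(weights, table, ann, cfg)
        b = pp.saturation_curve(weights, table, ann, cfg)
        assert np.array_equal(a.coverage, b.coverage)


class TestHighConfidence:
    def test_half_weight_gene_excluded_at_95_percent(self, one_barcode_per_gene):
        """A gene drawn with probability ~0.5 per realization appears in ~half
        the repetitions, far below the 95 % requirement."""
        _, table, ann = one_barcode_per_gene
        bcs = table.barcodes[:2]
        weights = {bcs[0]: 0.5, bcs[1]: 0.5}
        cfg = pp.SimulationConfig(seed=5, well_grid=(1,), reps=250, K=1.0)
        curve = pp.saturation_curve(weights, table, ann, cfg)
        assert curve.high_confidence_counts[0] == 0

    def test_certain_gene_always_included(self, one_barcode_per_gene):
        _, table, ann = one_barcode_per_gene
        bc = table.barcodes[0]
        cfg = pp.SimulationConfig(seed=5, well_grid=(3,), reps=100, K=1.0)
        curve = pp.saturation_curve({bc: 1.0}, table, ann, cfg)
        assert curve.high_confidence_counts[0] == 1

    def test_zero_threshold_is_union_over_reps(self, one_barcode_per_gene):
        weights, table, ann = one_barcode_per_gene
        cfg = pp.SimulationConfig(seed=5, well_grid=(30,), reps=50, K=1.0,
                                  hc_threshold=0.95)
        curve = pp.saturation_curve(weights, table, ann, cfg)
        union = curve.high_confidence_genes(30, threshold=0.0)
        assert union == {g for g, c in zip(curve.gene_ids,
                                           curve.presence_counts[0]) if c > 0}
        assert curve.high_confidence_genes(30) <= union

    def test_high_confidence_count_below_mean_coverage(self, one_barcode_per_gene):
        weights, table, ann = one_barcode_per_gene
        cfg = pp.SimulationConfig(seed=5, well_grid=(50, 150), reps=100)
        curve = pp.saturation_curve(weights, table, ann, cfg)
        assert (curve.high_confidence_counts <= curve.mean + 1e-9).all()


class TestResidualsAndIncrementalEfficiency:
    def _curve(self, one_barcode_per_gene, grid=(50, 100, 200)):
        weights, table, ann = one_barcode_per_gene
        cfg = pp.SimulationConfig(seed=7, well_grid=grid, reps=100)
        return pp.saturation_curve(weights, table, ann, cfg)

    def test_identical_curves_have_zero_residual(self, one_barcode_per_gene):
        curve = self._curve(one_barcode_per_gene)
        r = pp.residuals(curve.well_grid, curve.mean, curve)
        assert np.allclose(r["residual"], 0.0)

    def test_constant_offset_appears_in_residuals(self, one_barcode_per_gene):
        curve = self._curve(one_barcode_per_gene)
        r = pp.residuals(curve.well_grid, curve.mean + 5, curve)
        assert np.allclose(r["residual"], 5.0)

    def test_disjoint_grids_raise(self, one_barcode_per_gene):
        curve = self._curve(one_barcode_per_gene)
        with pytest.raises(ValidationError):
            pp.residuals(np.array([10_000.0]), np.array([1.0]), curve)

    def test_coupon_collector_slope_matches_derivative(self, one_barcode_per_gene):
        """Central-difference slope tracks d/db [G(1-(1-1/G)^b)]."""
        curve = self._curve(one_barcode_per_gene, grid=tuple(range(20, 201, 20)))
        slope, _ = pp.incremental_efficiency(curve)
        G = 100.0
        b = curve.well_grid.astype(float)
        analytic = -G * (1 - 1 / G) ** b * np.log(1 - 1 / G)
        inner = slice(1, -1)  # central differences are exact only inside
        assert np.allclose(slope[inner], analytic[inner], atol=0.06)

    def test_flat_curve_stops_at_first_grid_point(self, one_barcode_per_gene):
        weights, table, ann = one_barcode_per_gene
        bc = table.barcodes[0]
        cfg = pp.SimulationConfig(seed=5, well_grid=(50, 100, 150), reps=20)
        curve = pp.saturation_curve({bc: 1.0}, table, ann, cfg)
        _, w_star = pp.incremental_efficiency(curve)
        assert w_star == 50

    def test_steep_curve_has_no_stopping_point(self, one_barcode_per_gene):
        curve = self._curve(one_barcode_per_gene, grid=(10, 20, 30))
        _, w_star = pp.incremental_efficiency(curve, threshold=2e-3)
        assert w_star is None
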