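"""Monte Carlo saturation modeling of ordered-collection assembly.

The model predicts how many genes an ordered collection of ``w`` sorted wells
will cover, given (i) the barcode abundance distribution of the initial pool
(from BarSeq of t0-style samples), (ii) the barcode -> insertion lookup, and
(iii) an assembly efficiency ``K`` — the fraction of sorted wells that yield
a barcode usable for a condensed collection, estimated from collection
statistics as K = P(bpw = 1) x f_single.

Each simulation draws ``b = round(K * w)`` barcodes i.i.d. with replacement,
weighted by relative abundance (unmapped barcodes are filtered out first),
locates their insertions and counts the genes disrupted under the middle-85 %
rule.  Repeating 250 times per collection size yields a mean curve with a
percentile confidence band, plus the *high-confidence* gene set — genes
covered in at least 95 % of simulations.  Counterfactual scenarios set the
weights equal (unbiased pool) and/or K = 1 (perfect assembly).

For equal (and in fact arbitrary) weights the expected coverage has the
coupon-collector closed form  E[C(b)] = sum_g (1 - (1 - p_g)^b)  with ``p_g``
the total weight of barcodes disrupting gene g; it serves as the analytic
cross-check for the Monte Carlo path, which is retained because the
high-confidence sets and bands need realizations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .coverage import gene_hits
from .errors import ValidationError
from .io import GeneAnnotation, InsertionTable
from .mapping import AssemblyStats, filter_insertion_sites


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one saturation simulation run."""

    seed: int
    well_grid: tuple[int, ...]
    reps: int = 250
    K: float = 1.0
    equalized: bool = False
    hc_threshold: float = 0.95
    inc_threshold: float = 2e-3
    site_filter_threshold: float = 0.25

    def __post_init__(self) -> None:
        if not 0 < self.K <= 1:
            raise ValidationError("K must lie in (0, 1]")
        if self.reps < 1:
            raise ValidationError("reps must be >= 1")
        if not 0 <= self.hc_threshold <= 1:
            raise ValidationError("hc_threshold must lie in [0, 1]")
        object.__setattr__(self, "well_grid", tuple(int(w) for w in self.well_grid))


def default_well_grid(n_plates: int, step_plates: int = 5) -> tuple[int, ...]:
    """Default collection-size grid: one point per ``step_plates`` plates.

    Small collections fall back to a per-plate grid so the curve always has
    enough points for finite differences.
    """
    if n_plates < 2 * step_plates:
        step_plates = 1
    steps = np.arange(step_plates, n_plates + 1, step_plates)
    return tuple(int(96 * s) for s in steps)


@dataclass
class SaturationCurve:
    """Simulated coverage vs collection size, with band and confidence data."""

    well_grid: np.ndarray          # collection sizes w (wells)
    draws: np.ndarray              # b = round(K * w) per grid point
    mean: np.ndarray               # mean coverage over reps
    band_lo: np.ndarray            # 2.5th percentile over reps
    band_hi: np.ndarray            # 97.5th percentile over reps
    coverage: np.ndarray           # (reps, n_w) coverage realizations
    presence_counts: np.ndarray    # (n_w, n_genes) reps in which gene covered
    gene_ids: list[str]            # all annotated genes, fixed order
    total_genes: int
    pool_covered_genes: int        # genes coverable by the initial pool
    reps: int
    config: SimulationConfig

    def high_confidence_genes(self, w: int, threshold: float | None = None) -> set[str]:
        """Genes covered in >= threshold x reps of simulations at size w."""
        threshold = self.config.hc_threshold if threshold is None else threshold
        i = int(np.where(self.well_grid == w)[0][0])
        counts = self.presence_counts[i]
        if threshold == 0:
            mask = counts > 0
        else:
            mask = counts >= threshold * self.reps
        return {g for g, m in zip(self.gene_ids, mask) if m}

    @property
    def high_confidence_counts(self) -> np.ndarray:
        """High-confidence gene count per grid point."""
        thr = self.config.hc_threshold
        if thr == 0:
            return (self.presence_counts > 0).sum(axis=1)
        return (self.presence_counts >= thr * self.reps).sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "wells": self.well_grid,
                "draws": self.draws,
                "mean_coverage": self.mean,
                "band_lo": self.band_lo,
                "band_hi": self.band_hi,
                "high_confidence": self.high_confidence_counts,
            }
        )


# ---------------------------------------------------------------------------
# assembly efficiency
# ---------------------------------------------------------------------------

def estimate_K(stats: AssemblyStats, warn_gap: float = 0.05) -> float:
    """Assembly efficiency K = P(bpw = 1) x f_single.

    When the direct estimator (fraction of wells classified usable) disagrees
    by more than ``warn_gap``, a warning is emitted — the factored estimator
    assumes barcode status is independent of barcodes-per-well.
    """
    K = stats.K
    if abs(K - stats.K_direct) > warn_gap:
        warnings.warn(
            f"factored K = {K:.3f} differs from direct estimate "
            f"{stats.K_direct:.3f} by more than {warn_gap}",
            stacklevel=2,
        )
    return K


# ---------------------------------------------------------------------------
# drawing and the closed form
# ---------------------------------------------------------------------------

def draw_collection(
    weights: np.ndarray, b: int, rng: np.random.Generator
) -> np.ndarray:
    """Indices of ``b`` i.i.d. abundance-weighted draws with replacement."""
    if b == 0:
        return np.empty(0, dtype=np.int64)
    return rng.choice(len(weights), size=b, p=weights)


def expected_coverage(gene_weights: np.ndarray, b: int | np.ndarray) -> np.ndarray:
    """Closed-form expected coverage: sum_g (1 - (1 - p_g)^b).

    ``gene_weights[g]`` is the total draw weight of barcodes disrupting gene
    g.  Exact for i.i.d. draws with replacement, any weighting.
    """
    b = np.asarray(b)[..., None]
    return np.sum(1.0 - (1.0 - np.asarray(gene_weights)) ** b, axis=-1)


def _build_draw_pool(
    weights: Mapping[str, float],
    insertions: InsertionTable,
    annotation: GeneAnnotation,
    equalized: bool,
    site_filter_threshold: float,
) -> tuple[list[str], np.ndarray, list[np.ndarray], list[str]]:
    """Useful-barcode draw pool and per-barcode eligible gene index arrays.

    The pool is restricted to barcodes with a single defined chromosomal
    insertion site after the minority-site filter — the strains a condensed
    collection can use.  Unmapped barcodes, multi-site barcodes and
    vector-integrated barcodes are excluded: the assembly efficiency
    K = P(bpw = 1) x f_single already prices their loss into the
    wells-to-draws conversion, so each draw models one useful well.
    """
    filtered = filter_insertion_sites(insertions, site_filter_threshold)
    plasmids = set(filtered.contigs.plasmids)
    per_bc = filtered.records.groupby("barcode")
    useful = set(
        per_bc.size()[per_bc.size() == 1].index
    ) - set(
        filtered.records.loc[
            filtered.records["contig"].isin(plasmids), "barcode"
        ]
    )
    pool_bcs = [bc for bc in weights if bc in useful]
    if not pool_bcs:
        raise ValidationError("no mapped barcodes in the abundance table")
    w = np.array([weights[bc] for bc in pool_bcs], dtype=float)
    if equalized:
        w = np.ones_like(w)
    if w.sum() <= 0:
        raise ValidationError("abundance weights must have positive total")
    w = w / w.sum()

    gene_ids = annotation.gene_ids
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    hits = gene_hits(filtered, annotation, useful)
    eligible = hits[hits["eligible"]] if len(hits) else hits
    genes_of: dict[str, list[int]] = {}
    for rec in eligible.itertuples(index=False):
        genes_of.setdefault(rec.barcode, []).append(gene_index[rec.gene_id])
    gene_arrays = [
        np.array(sorted(set(genes_of.get(bc, []))), dtype=np.int64)
        for bc in pool_bcs
    ]
    return pool_bcs, w, gene_arrays, gene_ids


def gene_weight_totals(
    weights: Mapping[str, float],
    insertions: InsertionTable,
    annotation: GeneAnnotation,
    equalized: bool = False,
    site_filter_threshold: float = 0.25,
) -> np.ndarray:
    """Total normalized draw weight p_g per annotated gene."""
    _, w, gene_arrays, gene_ids = _build_draw_pool(
        weights, insertions, annotation, equalized, site_filter_threshold
    )
    p = np.zeros(len(gene_ids))
    for wi, genes in zip(w, gene_arrays):
        p[genes] += wi
    return p


# ---------------------------------------------------------------------------
# the simulation
# ---------------------------------------------------------------------------

def saturation_curve(
    weights: Mapping[str, float],
    insertions: InsertionTable,
    annotation: GeneAnnotation,
    config: SimulationConfig,
) -> SaturationCurve:
    """Simulate coverage over the collection-size grid.

    Within each repetition the draws are nested: one maximal draw sequence is
    generated and each grid point reads its prefix, so curves are monotone
    per repetition and scaling K scales the curve along the well axis exactly
    (the run at efficiency K and size w uses the same draws as the run at
    K = 1 and size K x w).
    """
    pool_bcs, w_probs, gene_arrays, gene_ids = _build_draw_pool(
        weights, insertions, annotation, config.equalized,
        config.site_filter_threshold,
    )
    n_genes = len(gene_ids)
    nonempty = [g for g in gene_arrays if len(g)]
    pool_covered = int(len(np.unique(np.concatenate(nonempty)))) if nonempty else 0

    well_grid = np.asarray(config.well_grid, dtype=np.int64)
    draws_grid = np.rint(config.K * well_grid).astype(np.int64)
    b_max = int(draws_grid.max(initial=0))

    # first gene hit per barcode draw, per repetition
    n_w = len(well_grid)
    coverage = np.zeros((config.reps, n_w), dtype=np.int64)
    presence_counts = np.zeros((n_w, n_genes), dtype=np.int64)

    for rep in range(config.reps):
        rng = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(rep,))
        )
        draws = draw_collection(w_probs, b_max, rng)
        # first draw index of each barcode
        first_bc = np.full(len(pool_bcs), np.iinfo(np.int64).max, dtype=np.int64)
        if b_max:
            np.minimum.at(first_bc, draws, np.arange(b_max, dtype=np.int64))
        # first disruption index of each gene
        first_gene = np.full(n_genes, np.iinfo(np.int64).max, dtype=np.int64)
        drawn = np.flatnonzero(first_bc < np.iinfo(np.int64).max)
        for bi in drawn:
            genes = gene_arrays[bi]
            if len(genes):
                np.minimum.at(first_gene, genes, first_bc[bi])
        for i, b in enumerate(draws_grid):
            hit = first_gene < b
            coverage[rep, i] = int(hit.sum())
            presence_counts[i] += hit

    mean = coverage.mean(axis=0)
    lo, hi = np.percentile(coverage, [2.5, 97.5], axis=0)
    return SaturationCurve(
        well_grid=well_grid,
        draws=draws_grid,
        mean=mean,
        band_lo=lo,
        band_hi=hi,
        coverage=coverage,
        presence_counts=presence_counts,
        gene_ids=gene_ids,
        total_genes=n_genes,
        pool_covered_genes=pool_covered,
        reps=config.reps,
        config=config,
    )


# ---------------------------------------------------------------------------
# residuals and incremental efficiency
# ---------------------------------------------------------------------------

def residuals(
    true_wells: np.ndarray,
    true_coverage: np.ndarray,
    curve: SaturationCurve,
) -> pd.DataFrame:
    """Residual true(w) - simulated mean(w) on the true curve's grid.

    The simulated mean is interpolated linearly between its grid points;
    true grid points outside the simulated range raise.
    """
    true_wells = np.asarray(true_wells, dtype=float)
    true_coverage = np.asarray(true_coverage, dtype=float)
    lo, hi = curve.well_grid.min(), curve.well_grid.max()
    inside = (true_wells >= lo) & (true_wells <= hi)
    if not inside.any():
        raise ValidationError("true and simulated curves share no well range")
    tw, tc = true_wells[inside], true_coverage[inside]
    sim = np.interp(tw, curve.well_grid, curve.mean)
    return pd.DataFrame(
        {"wells": tw, "true": tc, "simulated": sim, "residual": tc - sim}
    )


def incremental_efficiency(
    curve: SaturationCurve, threshold: float | None = None
) -> tuple[np.ndarray, int | None]:
    """Coverage gained per well added, and the practical stopping size.

    The slope is the central finite difference of mean coverage with respect
    to w; the stopping size w* is the smallest grid point whose slope falls
    below the threshold (default 2e-3 genes/well), or None if the curve never
    flattens that far.
    """
    threshold = curve.config.inc_threshold if threshold is None else threshold
    w = curve.well_grid.astype(float)
    if len(w) < 2:
        raise ValidationError("incremental efficiency needs >= 2 grid points")
    slope = np.gradient(curve.mean.astype(float), w)
    if (np.diff(curve.mean) < -np.maximum(3.0, 0.05 * curve.mean[:-1])).any():
        warnings.warn("mean coverage decreases beyond Monte Carlo jitter",
                      stacklevel=2)
    below = np.flatnonzero(slope < threshold)
    w_star = int(w[below[0]]) if len(below) else None
    return slope, w_star
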