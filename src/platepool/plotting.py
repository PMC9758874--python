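"""Plot helpers for saturation curves and growth-metric scatter plots."""

from __future__ import annotations

import numpy as np

from .saturation import SaturationCurve, incremental_efficiency


def plot_saturation(curve: SaturationCurve, ax=None, label: str | None = None,
                    color: str | None = None):
    """Mean coverage vs collection size with the 95 % percentile band."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.fill_between(curve.well_grid, curve.band_lo, curve.band_hi,
                    alpha=0.25, color=color)
    ax.plot(curve.well_grid, curve.mean, label=label, color=color)
    ax.axhline(curve.total_genes, color="k", lw=0.8)
    ax.axhline(curve.pool_covered_genes, color="r", ls="--", lw=0.8)
    ax.set_xlabel("collection size (wells)")
    ax.set_ylabel("genes covered")
    if label:
        ax.legend()
    return ax


def plot_incremental(curve: SaturationCurve, ax=None, threshold: float | None = None):
    """Coverage gained per well added, with the practical-limit threshold."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    slope, w_star = incremental_efficiency(curve, threshold)
    ax.semilogy(curve.well_grid, np.maximum(slope, 1e-12))
    thr = curve.config.inc_threshold if threshold is None else threshold
    ax.axhline(thr, color="k", ls="--", lw=0.8)
    if w_star is not None:
        ax.axvline(w_star, color="k", ls=":", lw=0.8)
    ax.set_xlabel("collection size (wells)")
    ax.set_ylabel("genes per added well")
    return ax


def plot_growth_outliers(flagged, mean, cov, ax=None, k: float = 3.0):
    """Scatter of (max rate, max OD) with the k-sigma wild-type ellipse."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ok = flagged[~flagged["outlier"].fillna(False)]
    bad = flagged[flagged["outlier"].fillna(False)]
    ax.scatter(ok["max_rate"], ok["max_od"], s=12, c="gray", label="within")
    ax.scatter(bad["max_rate"], bad["max_od"], s=16, c="crimson", label="outlier")
    # k-sigma covariance ellipse
    vals, vecs = np.linalg.eigh(np.asarray(cov, float))
    theta = np.linspace(0, 2 * np.pi, 200)
    circle = np.stack([np.cos(theta), np.sin(theta)])
    ellipse = (vecs @ (k * np.sqrt(vals)[:, None] * circle)).T + np.asarray(mean)
    ax.plot(ellipse[:, 0], ellipse[:, 1], "k--", lw=0.8)
    ax.set_xlabel("max growth rate (1/h)")
    ax.set_ylabel("max OD600")
    ax.legend()
    return ax
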