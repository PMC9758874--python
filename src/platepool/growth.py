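"""Growth-curve metrics and outlier calling against wild-type controls.

The maximum growth rate of a well is the largest slope of ln(OD600) with
respect to time over a sliding window of 5 consecutive time points, each
window fitted by ordinary least squares; the maximum OD600 is taken on a
width-3 median-filtered, blank-subtracted series to suppress single-read
spikes.  Mutants are flagged when their (max rate, max OD) point falls more
than 3 standard deviations — Mahalanobis distance with the full covariance —
from the wild-type control distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import medfilt

from .errors import ValidationError
from .io import GrowthCurve, GrowthCurveSet


@dataclass(frozen=True)
class GrowthMetrics:
    plate: str
    well: str
    strain: str
    max_rate: float          # h^-1, largest windowed slope of ln(OD)
    t_max_rate: float        # window-center time of the max slope, h
    max_od: float            # maximum of the median-filtered series
    t_max_od: float
    window: int
    defined: bool = True
    reason: str = ""


def _window_slope(t: np.ndarray, ln_od: np.ndarray) -> float:
    """OLS slope of ln(OD) on time for one window."""
    tm, ym = t.mean(), ln_od.mean()
    dt = t - tm
    return float(np.dot(dt, ln_od - ym) / np.dot(dt, dt))


def compute_metrics(
    curve: GrowthCurve, window: int = 5, od_floor: float = 0.005
) -> GrowthMetrics:
    """Per-well metrics from a blank-subtracted OD600 time series.

    Windows containing any reading at or below ``od_floor`` are skipped
    (the log of near-blank readings is undefined or dominated by noise).
    Metrics are undefined when fewer than ``window`` consecutive valid points
    exist.
    """
    od = curve.od600 - curve.blank
    t = curve.time_h
    if len(t) < window:
        return GrowthMetrics(curve.plate, curve.well, curve.strain,
                             np.nan, np.nan, np.nan, np.nan, window,
                             defined=False, reason=f"fewer than {window} points")
    smoothed = medfilt(od, kernel_size=3)
    i_max = int(np.argmax(smoothed))
    max_od, t_max_od = float(smoothed[i_max]), float(t[i_max])

    valid = od > od_floor
    best_slope = -np.inf
    best_t = np.nan
    ln_od = np.where(valid, np.log(np.where(valid, od, 1.0)), np.nan)
    for s in range(len(t) - window + 1):
        sl = slice(s, s + window)
        if not valid[sl].all():
            continue
        slope = _window_slope(t[sl], ln_od[sl])
        if slope > best_slope:
            best_slope = slope
            best_t = float(t[sl].mean())
    if not np.isfinite(best_slope):
        return GrowthMetrics(curve.plate, curve.well, curve.strain,
                             np.nan, np.nan, max_od, t_max_od, window,
                             defined=False,
                             reason="no window with all OD above the floor")
    return GrowthMetrics(curve.plate, curve.well, curve.strain,
                         best_slope, best_t, max_od, t_max_od, window)


def metrics_table(
    curves: GrowthCurveSet, window: int = 5, od_floor: float = 0.005
) -> pd.DataFrame:
    rows = [compute_metrics(c, window, od_floor) for c in curves.curves]
    return pd.DataFrame([r.__dict__ for r in rows])


def wildtype_distribution(
    control_metrics: pd.DataFrame,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample mean and unbiased covariance of (max rate, max OD) of controls."""
    df = control_metrics[control_metrics["defined"]]
    if len(df) < 3:
        raise ValidationError("need >= 3 control wells with defined metrics")
    x = df[["max_rate", "max_od"]].to_numpy(float)
    mean = x.mean(axis=0)
    cov = np.cov(x, rowvar=False, ddof=1)
    return mean, cov


def flag_outliers(
    metrics: pd.DataFrame,
    mean: np.ndarray,
    cov: np.ndarray,
    k: float = 3.0,
) -> pd.DataFrame:
    """Mahalanobis distance of each well from the wild-type distribution.

    Wells farther than ``k`` (default 3, the 3-standard-deviation ellipse)
    are flagged.  Returns the metrics table with ``distance`` and ``outlier``
    columns added; wells with undefined metrics get NA distance.
    """
    cov = np.asarray(cov, float)
    if np.linalg.matrix_rank(cov) < 2:
        raise ValidationError(
            "control covariance is singular; controls must vary independently "
            "in both metrics for a Mahalanobis distance to be defined"
        )
    cov_inv = np.linalg.inv(cov)
    out = metrics.copy()
    x = out[["max_rate", "max_od"]].to_numpy(float)
    d = x - np.asarray(mean, float)
    dist = np.sqrt(np.einsum("ij,jk,ik->i", d, cov_inv, d))
    dist[~out["defined"].to_numpy(bool)] = np.nan
    out["distance"] = dist
    out["outlier"] = dist > k
    return out
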