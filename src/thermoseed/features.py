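"""Characteristic-parameter extraction from relative-temperature curves.

Each seed's rT(t) series is reduced to 13 scalars: the extrema of the
smoothed curve within the imbibition window (rT_max, rT_min and their
times), the sharp-decline onset (rT_drop, trT_drop), and the smoothed
values at the seven fixed times 0 h, 20 h, ..., 120 h.  A second,
shorter representation — the raw rT values every 10 min over the first
three hours (19 values) — feeds the early-classification model that
predicts viability before the seeds are committed to germination.

The extremum search is restricted to a configurable imbibition window
(default: the first 300 min).  Over the full five days the slow
post-minimum plateau can drift below the imbibition minimum, so global
extrema would no longer describe the water-uptake kinetics that carry
the viability signal.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .thermo import TemperatureCurve

__all__ = [
    "CurveFeatures",
    "FeatureParams",
    "FEATURE_NAMES",
    "EARLY_VECTOR_NAMES",
    "smooth",
    "detect_drop",
    "extract_features",
    "extract_early_vector",
    "features_table",
    "early_vector_table",
]

logger = logging.getLogger(__name__)

FEATURE_NAMES = (
    "rT_max", "trT_max", "rT_drop", "trT_drop", "rT_min", "trT_min",
    "rT_0h", "rT_20h", "rT_40h", "rT_60h", "rT_80h", "rT_100h", "rT_120h",
)

EARLY_VECTOR_NAMES = tuple(f"rT_{t}min" for t in range(0, 181, 10))

_FIXED_HOURS = (0, 20, 40, 60, 80, 100, 120)


@dataclass
class FeatureParams:
    """Extraction tunables.

    smooth_window : odd number of frames for the centered moving
        average (5 frames = 25 min at the default cadence).
    search_window_min : imbibition window for extrema and drop
        detection, minutes.
    drop_theta_c_per_min : slope threshold for the sharp decline; the
        discrete derivative must fall strictly below ``-theta``.
    drop_k : number of consecutive qualifying frames required.
    impute_missing_drop : when the drop is not detected, fill the drop
        fields with the window-end time and value (logged) so that
        downstream classification sees a complete vector.
    """

    smooth_window: int = 5
    search_window_min: float = 300.0
    drop_theta_c_per_min: float = 0.005
    drop_k: int = 3
    impute_missing_drop: bool = True


@dataclass
class CurveFeatures:
    """The 13 characteristic parameters of one curve (times in minutes).

    Fields that cannot be computed (undetected drop without imputation,
    fixed-time values beyond the curve's coverage) are NaN.
    """

    seed_id: int | str
    rT_max: float
    trT_max: float
    rT_drop: float
    trT_drop: float
    rT_min: float
    trT_min: float
    rT_0h: float
    rT_20h: float
    rT_40h: float
    rT_60h: float
    rT_80h: float
    rT_100h: float
    rT_120h: float
    drop_detected: bool = True
    drop_imputed: bool = False

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


def smooth(series: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with truncated windows at the edges.

    ``window`` must be odd and >= 1; ``window=1`` is the identity.
    """
    series = np.asarray(series, dtype=float)
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 1")
    n = series.size
    if window > n:
        raise ValueError(f"window {window} exceeds series length {n}")
    if window == 1:
        return series.copy()
    half = window // 2
    csum = np.concatenate(([0.0], np.cumsum(series)))
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def detect_drop(smoothed: np.ndarray, times_min: np.ndarray,
                theta_c_per_min: float, k: int
                ) -> tuple[float, float] | None:
    """Earliest onset of a sustained sharp decline.

    Returns ``(trT_drop, rT_drop)`` for the earliest time whose discrete
    forward derivative stays strictly below ``-theta`` for ``k``
    consecutive frames, or ``None`` when no such run exists (a slope of
    exactly ``-theta`` does not qualify).
    """
    if theta_c_per_min <= 0:
        raise ValueError("theta must be positive")
    if k < 1:
        raise ValueError("k must be >= 1")
    smoothed = np.asarray(smoothed, dtype=float)
    times_min = np.asarray(times_min, dtype=float)
    if smoothed.size < k + 1:
        return None
    deriv = np.diff(smoothed) / np.diff(times_min)
    qualifying = deriv < -theta_c_per_min
    run = 0
    for i, q in enumerate(qualifying):
        run = run + 1 if q else 0
        if run == k:
            start = i - k + 1
            return float(times_min[start]), float(smoothed[start])
    return None


def _nearest_index(times: np.ndarray, t: float) -> int:
    return int(np.argmin(np.abs(times - t)))


def extract_features(curve: TemperatureCurve,
                     params: FeatureParams | None = None) -> CurveFeatures:
    """Reduce one curve to its 13 characteristic parameters.

    Extrema are the smoothed curve's max/min within the imbibition
    window, with ties broken toward the earliest time.  Fixed-time
    values are the smoothed curve at the grid point nearest each
    k-hour mark; marks beyond the curve's coverage are NaN.  Frames
    after the 120 h mark never influence any feature.
    """
    if params is None:
        params = FeatureParams()
    times = curve.times_min
    series = curve.r_t
    # coverage cap: nothing after the 120 h mark may leak into features
    interval = times[1] - times[0] if times.size > 1 else 1.0
    keep = times <= 120.0 * 60.0 + 1e-9
    times = times[keep]
    series = series[keep]

    window = min(params.smooth_window, times.size if times.size % 2 else times.size - 1)
    smoothed = smooth(series, max(window, 1))

    in_win = times <= params.search_window_min
    if not in_win.any():
        raise ValueError("curve does not cover the extremum search window")
    win_t = times[in_win]
    win_s = smoothed[in_win]
    # earliest attainment wins ties; tolerance absorbs smoothing round-off
    tol = 1e-9 * max(1.0, float(np.abs(win_s).max()))
    i_max = int(np.argmax(win_s >= win_s.max() - tol))
    i_min = int(np.argmax(win_s <= win_s.min() + tol))

    drop = detect_drop(win_s, win_t, params.drop_theta_c_per_min,
                       params.drop_k)
    drop_detected = drop is not None
    drop_imputed = False
    if drop is None:
        if params.impute_missing_drop:
            drop = (float(win_t[-1]), float(win_s[-1]))
            drop_imputed = True
            logger.info("seed %s: no sharp decline detected; drop fields "
                        "imputed with the window end", curve.seed_id)
        else:
            drop = (math.nan, math.nan)
            logger.warning("seed %s: no sharp decline detected", curve.seed_id)

    fixed = {}
    for hours in _FIXED_HOURS:
        t = hours * 60.0
        # a mark is covered if the grid reaches within one frame of it
        # (the standard 1440-frame run ends at 7195 min, one frame shy
        # of the 120 h mark)
        if t - times[-1] > interval + 1e-9:
            fixed[f"rT_{hours}h"] = math.nan
        else:
            fixed[f"rT_{hours}h"] = float(smoothed[_nearest_index(times, t)])

    return CurveFeatures(
        seed_id=curve.seed_id,
        rT_max=float(win_s[i_max]), trT_max=float(win_t[i_max]),
        rT_drop=drop[1], trT_drop=drop[0],
        rT_min=float(win_s[i_min]), trT_min=float(win_t[i_min]),
        drop_detected=drop_detected, drop_imputed=drop_imputed,
        **fixed,
    )


def extract_early_vector(curve: TemperatureCurve) -> np.ndarray:
    """Raw rT at t = 0, 10, ..., 180 min (19 values).

    Values come from the unsmoothed curve at the matching grid points
    (every 2nd frame at the 5-min cadence); the curve must cover the
    first three hours on a grid aligned with the 10-min marks.
    """
    times = curve.times_min
    if times[-1] < 180.0 - 1e-9:
        raise ValueError(
            f"seed {curve.seed_id}: curve covers only {times[-1]:.0f} min; "
            "the early vector needs 180 min"
        )
    out = np.empty(19)
    for j, t in enumerate(range(0, 181, 10)):
        i = _nearest_index(times, t)
        if abs(times[i] - t) > 1e-6:
            raise ValueError(
                f"seed {curve.seed_id}: frame grid has no sample at "
                f"t={t} min (nearest is {times[i]} min)"
            )
        out[j] = curve.r_t[i]
    return out


def features_table(curves: list[TemperatureCurve],
                   params: FeatureParams | None = None) -> pd.DataFrame:
    """13-parameter feature matrix for a cohort, indexed by seed_id."""
    rows = []
    for curve in curves:
        feats = extract_features(curve, params)
        rows.append({"seed_id": feats.seed_id, **feats.as_dict(),
                     "drop_detected": feats.drop_detected})
    return pd.DataFrame(rows).set_index("seed_id")


def early_vector_table(curves: list[TemperatureCurve]) -> pd.DataFrame:
    """First-three-hours feature matrix (19 columns), indexed by seed_id."""
    rows = []
    for curve in curves:
        vec = extract_early_vector(curve)
        rows.append({"seed_id": curve.seed_id,
                     **dict(zip(EARLY_VECTOR_NAMES, vec))})
    return pd.DataFrame(rows).set_index("seed_id")
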