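"""Thermal-gray calibration and per-seed relative-temperature curves.

An 8-bit thermal raster encodes temperature linearly between two preset
values: gray 0 maps to ``t_min_c`` and gray 255 to ``t_max_c`` (defaults
21 and 27 degC, a 6 degC span, so one gray step is about 0.0235 degC).
A seed's measurement is the mean temperature over its central disk; the
surrounding filter-paper annulus provides the environment reference, and
the relative temperature

    rT(t) = T_seed(t) - T_env(t)

cancels ambient drift and the evaporative-cooling baseline that both
regions share, leaving the seed's own metabolic heat signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ThermalCalibration",
    "TemperatureCurve",
    "GapError",
    "gray_to_temperature",
    "region_mean_temperature",
    "build_curve",
]


class GapError(ValueError):
    """Raised when a run of missing frames is too long to interpolate."""


@dataclass(frozen=True)
class ThermalCalibration:
    """Linear gray <-> temperature mapping of an 8-bit thermal raster.

    ``span_only=True`` is an audit mode that omits the ``t_min_c``
    intercept and maps gray onto ``[0, t_max_c - t_min_c]``; relative
    temperatures are unaffected because the intercept cancels in the
    seed-minus-environment difference.
    """

    t_min_c: float = 21.0
    t_max_c: float = 27.0
    span_only: bool = False

    def __post_init__(self) -> None:
        if not self.t_min_c < self.t_max_c:
            raise ValueError(
                f"calibration requires t_min_c < t_max_c, got "
                f"({self.t_min_c}, {self.t_max_c})"
            )

    @property
    def span_c(self) -> float:
        return self.t_max_c - self.t_min_c

    @property
    def step_c(self) -> float:
        """Temperature increment of one gray level."""
        return self.span_c / 255.0


def gray_to_temperature(gray, cal: ThermalCalibration):
    """Convert gray values (scalar or array) to degC.

    Strictly increasing affine map; gray must lie in [0, 255].
    """
    g = np.asarray(gray, dtype=float)
    if np.any(g < 0) or np.any(g > 255):
        raise ValueError("gray values must lie in [0, 255]")
    t = g / 255.0 * cal.span_c
    if not cal.span_only:
        t = t + cal.t_min_c
    return t if t.ndim else float(t)


def region_mean_temperature(raster: np.ndarray, mask: np.ndarray,
                            cal: ThermalCalibration) -> float:
    """Mean temperature over the masked pixels of a thermal raster.

    By linearity this equals ``gray_to_temperature`` of the mean gray.
    """
    raster = np.asarray(raster)
    mask = np.asarray(mask, dtype=bool)
    if raster.shape != mask.shape:
        raise ValueError(
            f"raster shape {raster.shape} does not match mask shape {mask.shape}"
        )
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty mask")
    return float(gray_to_temperature(float(raster[mask].mean()), cal))


@dataclass
class TemperatureCurve:
    """Per-seed relative-temperature series on a uniform time grid."""

    seed_id: int | str
    times_min: np.ndarray
    r_t: np.ndarray
    t_seed: np.ndarray | None = None
    t_env: np.ndarray | None = None
    interpolated: np.ndarray | None = None
    saturation_fraction: float = 0.0
    label: str | None = field(default=None)

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.r_t = np.asarray(self.r_t, dtype=float)
        if self.times_min.shape != self.r_t.shape:
            raise ValueError("times and rT series must have equal length")

    @property
    def n_frames(self) -> int:
        return self.times_min.size

    @property
    def interval_min(self) -> float:
        if self.n_frames < 2:
            raise ValueError("need at least two frames for an interval")
        return float(self.times_min[1] - self.times_min[0])


def _interpolate_gaps(times: np.ndarray, values: np.ndarray,
                      max_gap: int) -> tuple[np.ndarray, np.ndarray]:
    """Linearly fill NaN runs of length <= max_gap; error otherwise."""
    missing = ~np.isfinite(values)
    if not missing.any():
        return values, missing
    # locate runs of consecutive missing frames
    idx = np.flatnonzero(missing)
    runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
    bad = [r for r in runs if r.size > max_gap]
    if bad:
        spans = [f"frames {r[0]}..{r[-1]}" for r in bad]
        raise GapError(
            f"missing-frame runs exceed max_gap={max_gap}: " + "; ".join(spans)
        )
    good = ~missing
    if good.sum() < 2:
        raise GapError("fewer than two valid frames; cannot interpolate")
    filled = values.copy()
    filled[missing] = np.interp(times[missing], times[good], values[good])
    return filled, missing


def build_curve(sequence, region, cal: ThermalCalibration | None = None,
                max_gap: int = 3) -> TemperatureCurve:
    """Assemble the rT(t) curve of one seed over a frame sequence.

    For every frame the seed temperature is the disk mean and the
    environment temperature the annulus mean, both in thermal-raster
    space.  Runs of up to ``max_gap`` missing frames are linearly
    interpolated and flagged; longer runs raise :class:`GapError`.
    Saturated pixels (gray 0 or 255) are included in the means but
    counted; a disk saturation fraction above 5% triggers a warning.
    """
    if cal is None:
        cal = sequence.calibration
    disk = region.thermal_disk
    annulus = region.thermal_annulus
    if disk is None or annulus is None:
        raise ValueError(
            f"seed {region.seed_id}: thermal-space disk/annulus masks missing; "
            "run map_to_thermal first"
        )
    times = np.asarray(sequence.times_min, dtype=float)
    n = times.size
    # raw temperature rasters (degC) skip the gray calibration entirely
    raw_temps = bool(getattr(sequence, "temperature_frames", False))
    t_seed = np.full(n, np.nan)
    t_env = np.full(n, np.nan)
    sat_px = 0
    disk_px_total = 0
    for i in range(n):
        raster = sequence.thermal(i)
        if raster is None:
            continue
        dvals = raster[disk]
        avals = raster[annulus]
        if raw_temps:
            t_seed[i] = float(dvals.mean())
            t_env[i] = float(avals.mean())
        else:
            t_seed[i] = gray_to_temperature(float(dvals.mean()), cal)
            t_env[i] = gray_to_temperature(float(avals.mean()), cal)
            sat_px += int(((dvals == 0) | (dvals == 255)).sum())
            disk_px_total += dvals.size
    t_seed, miss_s = _interpolate_gaps(times, t_seed, max_gap)
    t_env, _ = _interpolate_gaps(times, t_env, max_gap)
    sat_frac = sat_px / disk_px_total if disk_px_total else 0.0
    if sat_frac > 0.05:
        warnings.warn(
            f"seed {region.seed_id}: {sat_frac:.1%} of disk pixels saturated; "
            "temperatures may be clipped at the calibration presets",
            stacklevel=2,
        )
    return TemperatureCurve(
        seed_id=region.seed_id,
        times_min=times,
        r_t=t_seed - t_env,
        t_seed=t_seed,
        t_env=t_env,
        interpolated=miss_s,
        saturation_fraction=sat_frac,
    )
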