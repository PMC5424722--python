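"""Synthetic visible/thermal phantom sequences with known ground truth.

Real germination imagery of the kind this package analyses is rarely
shareable, so every pipeline stage is validated against a phantom: a
tray of bright convex seeds on darker filter paper (visible channel)
and class-conditional relative-temperature kinetics rendered into
quantized 8-bit thermal frames with ambient drift and sensor noise.

The curve grammar follows the imbibition thermodynamics of pea seeds:
rT starts near zero, shows an early local maximum, declines gently to a
sharp-drop onset, falls steeply to a minimum at the inflection point of
water uptake, then relaxes slowly toward a long-run plateau.  The three
viability classes (viable, aged, non-viable) differ in the depth of the
minimum and the timing of the sharp decline: aged seeds cool deepest,
non-viable seeds drop earliest and shallowest.

Default class templates place the curve landmarks at the group means
measured on a 120-seed pea cohort (41 viable / 32 aged / 47 non-viable),
with per-seed jitter set to one third of the observed group SDs so that
the classes remain learnable at that cohort size; this is a synthesis
choice of the generator, not a measured property of any real seed lot.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .imaging import AffineTransform, FrameSequence, LayoutError, map_to_thermal
from .thermo import ThermalCalibration

__all__ = [
    "SceneConfig",
    "CurveTemplate",
    "GroundTruth",
    "DEFAULT_TEMPLATES",
    "ROOT_LENGTH_BANDS",
    "sample_curve",
    "make_labelled_cohort",
    "render_sequence",
    "write_ground_truth",
]

#: Root-length bands (cm) defining the three viability classes.
ROOT_LENGTH_BANDS = {
    "viable": (1.6, 5.0),
    "aged": (0.1, 1.5),
    "non_viable": (0.0, 0.0),
}


@dataclass(frozen=True)
class SceneConfig:
    """Geometry, timing, calibration and noise of a phantom scene.

    Times are minutes; the default 5-min interval over 5 days gives
    1440 frame pairs.  Calibration presets default to the 21–27 degC
    window of the thermal camera with ambient at 24 degC, drifting as a
    slow sinusoid within ±0.4 degC (the incubator tolerance); seed and
    filter paper see the same drift, so rT is drift-free by design.
    """

    grid_rows: int = 4
    grid_cols: int = 5
    seed_radius_px: float = 14.0
    visible_size: tuple[int, int] = (600, 900)
    thermal_size: tuple[int, int] = (240, 320)
    frame_interval_min: float = 5.0
    duration_min: float = 7200.0
    t_min_c: float = 21.0
    t_max_c: float = 27.0
    ambient_c: float = 24.0
    ambient_drift_c: float = 0.4
    drift_period_min: float = 1440.0
    noise_sd_gray: float = 1.0
    texture_sd_gray: float = 4.0
    background_gray: float = 60.0
    seed_gray: float = 180.0
    n_reflections: int = 0
    reflection_amplitude_gray: float = 40.0
    reflection_sigma_px: float = 2.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows * self.grid_cols < 1:
            raise ValueError("grid must hold at least one seed")
        if not self.t_min_c < self.t_max_c:
            raise ValueError("require t_min_c < t_max_c")
        ratio = self.duration_min / self.frame_interval_min
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("duration_min must be divisible by frame_interval_min")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_min / self.frame_interval_min))

    @property
    def times_min(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_min

    @property
    def calibration(self) -> ThermalCalibration:
        return ThermalCalibration(self.t_min_c, self.t_max_c)

    @property
    def transform(self) -> AffineTransform:
        return AffineTransform.between(self.visible_size, self.thermal_size)


@dataclass(frozen=True)
class CurveTemplate:
    """Landmark parameterization of one viability class's rT kinetics.

    Temperatures are degC relative to the environment; times are
    minutes.  ``drop_fraction`` sets the value at the sharp-decline
    onset as a fraction of the peak-to-minimum fall (the gentle
    pre-drop dip; kept small so that the pre-drop slope never reaches
    the sharp-decline detection threshold).  After the minimum the
    curve rebounds by ``rebound_c`` over ``rebound_min`` minutes —
    the post-inflection warming, fastest in non-viable seeds — and
    then relaxes exponentially toward ``plateau_c``.  ``sd_*`` fields
    are per-seed Gaussian jitter SDs.
    """

    viability_class: str
    rt_start_c: float = 0.0
    rt_peak_c: float = 0.0
    rt_min_c: float = 0.0
    plateau_c: float = 0.0
    t_peak_min: float = 0.0
    t_drop_min: float = 0.0
    t_min_min: float = 0.0
    recovery_rate_c_per_min: float = 0.001
    drop_fraction: float = 0.15
    rebound_c: float = 0.0
    rebound_min: float = 120.0
    sd_rt_start: float = 0.0
    sd_rt_peak: float = 0.0
    sd_rt_min: float = 0.0
    sd_plateau: float = 0.0
    sd_t_peak: float = 0.0
    sd_t_drop: float = 0.0
    sd_t_min: float = 0.0

    def validate(self, duration_min: float | None = None) -> None:
        if not 0.0 <= self.t_peak_min <= self.t_drop_min <= self.t_min_min:
            raise ValueError(
                f"{self.viability_class}: timing must satisfy "
                "0 <= t_peak <= t_drop <= t_min, got "
                f"({self.t_peak_min}, {self.t_drop_min}, {self.t_min_min})"
            )
        if duration_min is not None and self.t_min_min > duration_min:
            raise ValueError(
                f"{self.viability_class}: t_min_min exceeds duration "
                f"{duration_min}"
            )
        if self.rt_min_c > min(self.rt_start_c, self.rt_peak_c) + 1e-12:
            raise ValueError(
                f"{self.viability_class}: rt_min_c must not exceed "
                "min(rt_start_c, rt_peak_c)"
            )


#: Class templates: landmark means from a 120-seed pea cohort (times are
#: frame indices x 5 min), jitter SDs at one third of the group SDs.
#: The aged start value is lowered below the aged peak to keep the
#: early-local-maximum grammar well defined.
DEFAULT_TEMPLATES: dict[str, CurveTemplate] = {
    "viable": CurveTemplate(
        viability_class="viable",
        rt_start_c=-0.2594, rt_peak_c=0.1376, rt_min_c=-1.0389,
        plateau_c=-1.1240, t_peak_min=19.0, t_drop_min=113.5,
        t_min_min=227.5, recovery_rate_c_per_min=0.001, rebound_c=0.20,
        sd_rt_start=0.1749, sd_rt_peak=0.0669, sd_rt_min=0.2363,
        sd_plateau=0.1967, sd_t_peak=4.35, sd_t_drop=7.49, sd_t_min=7.93,
    ),
    "aged": CurveTemplate(
        viability_class="aged",
        rt_start_c=0.1000, rt_peak_c=0.1838, rt_min_c=-1.4796,
        plateau_c=-1.1905, t_peak_min=8.75, t_drop_min=114.25,
        t_min_min=242.75, recovery_rate_c_per_min=0.001, rebound_c=0.30,
        sd_rt_start=0.2049, sd_rt_peak=0.0918, sd_rt_min=0.2572,
        sd_plateau=0.2045, sd_t_peak=2.92, sd_t_drop=6.23, sd_t_min=6.59,
    ),
    "non_viable": CurveTemplate(
        viability_class="non_viable",
        rt_start_c=0.0467, rt_peak_c=0.1770, rt_min_c=-0.5591,
        plateau_c=-0.9680, t_peak_min=8.5, t_drop_min=78.0,
        t_min_min=220.0, recovery_rate_c_per_min=0.001, rebound_c=0.40,
        sd_rt_start=0.1863, sd_rt_peak=0.0953, sd_rt_min=0.3059,
        sd_plateau=0.1697, sd_t_peak=3.16, sd_t_drop=4.94, sd_t_min=8.27,
    ),
}


def _smoothstep(u: np.ndarray) -> np.ndarray:
    """Cubic easing 3u^2 - 2u^3 on [0, 1]; zero slope at both ends."""
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def sample_curve(template: CurveTemplate, duration_min: float,
                 interval_min: float,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """Realize one seed's rT(t) series on the frame grid.

    The curve is piecewise smooth: eased rise from ``rt_start_c`` to a
    local maximum ``rt_peak_c`` at ``t_peak_min``; gentle decline to
    the sharp-drop onset at ``t_drop_min``; a steep front-loaded fall
    (fast at onset, easing into the minimum) to ``rt_min_c`` at
    ``t_min_min``; a rebound of ``rebound_c`` over ``rebound_min``
    minutes; then exponential relaxation toward ``plateau_c`` with
    initial rate ``recovery_rate_c_per_min``.  Landmark jitter is
    drawn from the template SDs; jittered landmarks are re-clipped to
    preserve the shape grammar, so with a non-negative rebound the
    realized minimum equals the (jittered) ``rt_min_c`` exactly at
    ``t_min_min``.
    """
    template.validate(duration_min)
    if rng is None:
        rng = np.random.default_rng(0)
    t = np.arange(int(round(duration_min / interval_min))) * interval_min

    def jit(value, sd):
        return value + (rng.normal(0.0, sd) if sd > 0 else 0.0)

    rt_start = jit(template.rt_start_c, template.sd_rt_start)
    rt_peak = jit(template.rt_peak_c, template.sd_rt_peak)
    rt_min = jit(template.rt_min_c, template.sd_rt_min)
    plateau = jit(template.plateau_c, template.sd_plateau)
    t_peak = jit(template.t_peak_min, template.sd_t_peak)
    t_drop = jit(template.t_drop_min, template.sd_t_drop)
    t_min = jit(template.t_min_min, template.sd_t_min)

    # re-establish the shape grammar after jitter
    t_peak = float(np.clip(t_peak, 0.0, duration_min))
    t_drop = float(np.clip(t_drop, t_peak, duration_min))
    t_min = float(np.clip(t_min, t_drop, duration_min))
    rt_peak = max(rt_peak, rt_start)
    rt_min = min(rt_min, rt_start, rt_peak)
    rt_drop = rt_peak - template.drop_fraction * (rt_peak - rt_min)

    out = np.empty_like(t)
    seg = t <= t_peak
    if t_peak > 0:
        out[seg] = rt_start + (rt_peak - rt_start) * _smoothstep(t[seg] / t_peak)
    else:
        out[seg] = rt_peak
    seg = (t > t_peak) & (t <= t_drop)
    if t_drop > t_peak:
        u = (t[seg] - t_peak) / (t_drop - t_peak)
        out[seg] = rt_peak + (rt_drop - rt_peak) * _smoothstep(u)
    else:
        out[seg] = rt_drop
    seg = (t > t_drop) & (t <= t_min)
    if t_min > t_drop:
        # front-loaded easing: steep right after onset, flat into the minimum
        u = (t[seg] - t_drop) / (t_min - t_drop)
        out[seg] = rt_drop + (rt_min - rt_drop) * (1.0 - (1.0 - u) ** 3)
    else:
        out[seg] = rt_min
    rt_reb = rt_min + max(template.rebound_c, 0.0)
    t_reb_end = t_min + max(template.rebound_min, 0.0)
    seg = (t > t_min) & (t <= t_reb_end)
    if t_reb_end > t_min:
        u = (t[seg] - t_min) / (t_reb_end - t_min)
        out[seg] = rt_min + (rt_reb - rt_min) * _smoothstep(u)
    seg = t > t_reb_end
    gap = abs(rt_reb - plateau)
    if gap < 1e-12:
        out[seg] = rt_reb
    else:
        rate = template.recovery_rate_c_per_min / gap
        out[seg] = plateau + (rt_reb - plateau) * np.exp(
            -rate * (t[seg] - t_reb_end))
    return out


@dataclass
class GroundTruth:
    """Everything known about one phantom seed."""

    seed_id: int
    viability_class: str
    root_length_cm: float
    curve: np.ndarray
    center_visible: tuple[float, float]
    radius_visible: float
    axes_visible: tuple[float, float]
    orientation_rad: float
    center_thermal: tuple[float, float]
    radius_thermal: float
    visible_mask: np.ndarray = field(repr=False, default=None)
    thermal_mask: np.ndarray = field(repr=False, default=None)


def _ellipse_mask(shape, center, axes, theta) -> np.ndarray:
    rr = np.arange(shape[0], dtype=float)[:, None] - center[0]
    cc = np.arange(shape[1], dtype=float)[None, :] - center[1]
    x = np.cos(theta) * cc + np.sin(theta) * rr
    y = -np.sin(theta) * cc + np.cos(theta) * rr
    return (x / axes[1]) ** 2 + (y / axes[0]) ** 2 <= 1.0


def _grid_centers(config: SceneConfig) -> list[tuple[float, float]]:
    h, w = config.visible_size
    margin_r = max(3.0 * config.seed_radius_px, 0.05 * h)
    margin_c = max(3.0 * config.seed_radius_px, 0.05 * w)
    rows = np.linspace(margin_r, h - margin_r, config.grid_rows)
    cols = np.linspace(margin_c, w - margin_c, config.grid_cols)
    return [(float(r), float(c)) for r in rows for c in cols]


def make_labelled_cohort(n_viable: int, n_aged: int, n_nonviable: int,
                         config: SceneConfig,
                         templates: dict[str, CurveTemplate] | None = None,
                         rng: np.random.Generator | None = None
                         ) -> list[GroundTruth]:
    """Draw a cohort of phantom seeds with classes, root lengths and curves.

    Root lengths are uniform within each class band (viable 1.6–5.0 cm,
    aged 0.1–1.5 cm, non-viable exactly 0).  Classes are shuffled over
    the tray grid; seed ids follow row-major tray order.
    """
    if min(n_viable, n_aged, n_nonviable) < 0:
        raise ValueError("class counts must be non-negative")
    total = n_viable + n_aged + n_nonviable
    capacity = config.grid_rows * config.grid_cols
    if total > capacity:
        raise LayoutError(
            f"cohort of {total} seeds exceeds tray capacity "
            f"{config.grid_rows}x{config.grid_cols}={capacity}"
        )
    if templates is None:
        templates = DEFAULT_TEMPLATES
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)

    classes = (["viable"] * n_viable + ["aged"] * n_aged
               + ["non_viable"] * n_nonviable)
    rng.shuffle(classes)
    centers = _grid_centers(config)[:total]
    transform = config.transform

    truths = []
    for sid, (cls, center) in enumerate(zip(classes, centers)):
        lo, hi = ROOT_LENGTH_BANDS[cls]
        root = float(rng.uniform(lo, hi)) if hi > lo else lo
        radius = config.seed_radius_px * float(rng.uniform(0.92, 1.08))
        ratio = float(rng.uniform(0.85, 1.0))
        theta = float(rng.uniform(0.0, math.pi))
        axes = (radius / math.sqrt(ratio), radius * math.sqrt(ratio))
        curve = sample_curve(templates[cls], config.duration_min,
                             config.frame_interval_min, rng)
        vis_mask = _ellipse_mask(config.visible_size, center, axes, theta)
        thermal_mask = map_to_thermal(vis_mask, transform,
                                      config.thermal_size, sid)
        tr, tc = transform.apply(center[0], center[1])
        truths.append(GroundTruth(
            seed_id=sid, viability_class=cls, root_length_cm=root,
            curve=curve, center_visible=center, radius_visible=radius,
            axes_visible=axes, orientation_rad=theta,
            center_thermal=(float(tr), float(tc)),
            radius_thermal=radius * float(np.sqrt(
                transform.scale_row * transform.scale_col)),
            visible_mask=vis_mask, thermal_mask=thermal_mask,
        ))
    return truths


def _quantize(temp_c: np.ndarray, cal: ThermalCalibration,
              noise: np.ndarray | None) -> tuple[np.ndarray, int]:
    gray = (temp_c - cal.t_min_c) / cal.span_c * 255.0
    if noise is not None:
        gray = gray + noise
    saturated = int(np.count_nonzero((gray < 0.0) | (gray > 255.0)))
    return np.rint(np.clip(gray, 0.0, 255.0)).astype(np.uint8), saturated


def render_sequence(config: SceneConfig, truths: list[GroundTruth],
                    out_dir: str | Path | None = None) -> FrameSequence:
    """Render a cohort into paired visible/thermal frame stacks.

    Visible frames: dark filter-paper background with optional bright
    reflection blobs, seeds as bright filled ellipses with static
    texture, plus per-frame sensor noise.  Thermal frames: quantized
    ambient (with sinusoidal drift) everywhere, plus each seed's rT
    inside its thermal footprint; temperatures outside the calibration
    window are clipped and counted in the sequence's saturation log.

    With ``out_dir`` set, frames are written as 8-bit grayscale PNGs
    together with a manifest CSV (frame paths, timestamps, calibration
    and the visible->thermal registration transform) and ground-truth
    CSVs.  The in-memory sequence is returned either way.
    """
    rng = np.random.default_rng(config.rng_seed)
    h, w = config.visible_size
    cal = config.calibration

    occupancy = np.zeros(config.visible_size, dtype=np.uint8)
    for truth in truths:
        occupancy += truth.visible_mask.astype(np.uint8)
    if occupancy.max(initial=0) > 1:
        raise LayoutError("seed footprints overlap in the visible raster")

    vis_base = np.full(config.visible_size, config.background_gray)
    for truth in truths:
        vis_base[truth.visible_mask] = config.seed_gray
        if config.texture_sd_gray > 0:
            n_px = int(truth.visible_mask.sum())
            vis_base[truth.visible_mask] += rng.normal(
                0.0, config.texture_sd_gray, n_px)
    any_seed = occupancy.astype(bool)
    for _ in range(config.n_reflections):
        for _attempt in range(50):
            r0 = rng.uniform(0.05 * h, 0.95 * h)
            c0 = rng.uniform(0.05 * w, 0.95 * w)
            if not any_seed[int(r0), int(c0)]:
                break
        d2 = _distance_sq(config.visible_size, (r0, c0))
        vis_base += config.reflection_amplitude_gray * np.exp(
            -d2 / (2.0 * config.reflection_sigma_px ** 2))

    times = config.times_min
    drift = config.ambient_drift_c * np.sin(
        2.0 * np.pi * times / config.drift_period_min)

    visible_frames = []
    thermal_frames = []
    saturation_count = 0
    for i in range(config.n_frames):
        frame = vis_base
        if config.noise_sd_gray > 0:
            frame = frame + rng.normal(0.0, config.noise_sd_gray,
                                       config.visible_size)
        visible_frames.append(
            np.rint(np.clip(frame, 0.0, 255.0)).astype(np.uint8))

        temp = np.full(config.thermal_size, config.ambient_c + drift[i])
        for truth in truths:
            temp[truth.thermal_mask] += truth.curve[i]
        noise = (rng.normal(0.0, config.noise_sd_gray, config.thermal_size)
                 if config.noise_sd_gray > 0 else None)
        gray, sat = _quantize(temp, cal, noise)
        saturation_count += sat
        thermal_frames.append(gray)

    seq = FrameSequence(times, cal, config.transform,
                        visible_frames=visible_frames,
                        thermal_frames=thermal_frames,
                        saturation_count=saturation_count)
    if out_dir is not None:
        _write_sequence(seq, config, truths, Path(out_dir))
    return seq


def _distance_sq(shape, center):
    rr = np.arange(shape[0], dtype=float)[:, None] - center[0]
    cc = np.arange(shape[1], dtype=float)[None, :] - center[1]
    return rr ** 2 + cc ** 2


def _write_sequence(seq: FrameSequence, config: SceneConfig,
                    truths: list[GroundTruth], out_dir: Path) -> None:
    import imageio.v3 as iio

    frames_dir = out_dir / "frames"
    frames_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, t in enumerate(seq.times_min):
        vis_path = f"frames/visible_{i:05d}.png"
        thr_path = f"frames/thermal_{i:05d}.png"
        iio.imwrite(out_dir / vis_path, seq.visible(i).astype(np.uint8))
        iio.imwrite(out_dir / thr_path, seq.thermal(i))
        rows.append({
            "frame_index": i, "time_min": float(t),
            "visible_path": vis_path, "thermal_path": thr_path,
            "t_min_c": config.t_min_c, "t_max_c": config.t_max_c,
            **config.transform.to_dict(),
        })
    pd.DataFrame(rows).to_csv(out_dir / "manifest.csv", index=False)
    write_ground_truth(truths, out_dir, config.frame_interval_min)


def write_ground_truth(truths: list[GroundTruth], out_dir: str | Path,
                       interval_min: float = 5.0) -> None:
    """Write ground-truth seed table and per-seed curve CSVs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([
        {"seed_id": t.seed_id, "class": t.viability_class,
         "root_length_cm": t.root_length_cm,
         "cx": t.center_visible[1], "cy": t.center_visible[0],
         "radius": t.radius_visible,
         "cx_thermal": t.center_thermal[1], "cy_thermal": t.center_thermal[0],
         "radius_thermal": t.radius_thermal}
        for t in truths
    ]).to_csv(out_dir / "ground_truth.csv", index=False)
    if truths:
        n = truths[0].curve.size
        long = pd.DataFrame({
            "seed_id": np.repeat([t.seed_id for t in truths], n),
            "time_min": np.tile(np.arange(n) * interval_min, len(truths)),
            "rT_c": np.concatenate([t.curve for t in truths]),
        })
        long.to_csv(out_dir / "true_curves.csv", index=False)
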