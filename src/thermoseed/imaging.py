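"""Frame-sequence handling and visible-light seed segmentation.

Seeds sit still on filter paper for the whole germination run, so the
reference (first) visible frame is segmented once and its per-seed
regions are reused for every frame.  Each seed gets three masks:

* the full segmented mask,
* a central *disk* of roughly one third of the seed area, used as the
  measurement region (it avoids the cool, partially mixed seed rim),
* a filter-paper *annulus* around the seed, excluding every seed mask,
  used as the local environment reference.

Visible and thermal rasters generally differ in size; an affine
(scale + offset) transform carries visible-space masks into thermal
pixel coordinates.  Coordinates are (row, col), 0-based, with pixel
centers at integer positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import feature as skfeature
from skimage import morphology as skmorph
from skimage.segmentation import flood

from .thermo import ThermalCalibration

__all__ = [
    "AffineTransform",
    "FrameSequence",
    "SeedRegion",
    "SegmentationParams",
    "LayoutError",
    "subtract_background",
    "segment_seeds",
    "make_disk",
    "make_annulus",
    "map_to_thermal",
    "build_regions",
]

logger = logging.getLogger(__name__)


class LayoutError(ValueError):
    """Raised when geometry is inconsistent (overlaps, off-raster masks)."""


@dataclass(frozen=True)
class AffineTransform:
    """Axis-aligned affine map (scale + offset) between pixel grids.

    Maps visible-space (row, col) to thermal-space coordinates:
    ``r' = r * scale_row + offset_row`` and likewise for columns.
    """

    scale_row: float = 1.0
    scale_col: float = 1.0
    offset_row: float = 0.0
    offset_col: float = 0.0

    def apply(self, rows, cols):
        rows = np.asarray(rows, dtype=float)
        cols = np.asarray(cols, dtype=float)
        return (rows * self.scale_row + self.offset_row,
                cols * self.scale_col + self.offset_col)

    @classmethod
    def between(cls, src_shape, dst_shape) -> "AffineTransform":
        """Pure scaling between two raster shapes (rows, cols)."""
        return cls(scale_row=dst_shape[0] / src_shape[0],
                   scale_col=dst_shape[1] / src_shape[1])

    def to_dict(self) -> dict:
        return {"scale_row": self.scale_row, "scale_col": self.scale_col,
                "offset_row": self.offset_row, "offset_col": self.offset_col}


def _to_grayscale(raster: np.ndarray) -> np.ndarray:
    """Collapse an RGB visible frame to luminance; pass gray through."""
    raster = np.asarray(raster)
    if raster.ndim == 3:
        # ITU-R 601 luma weights
        return raster[..., :3] @ np.array([0.299, 0.587, 0.114])
    return raster


class FrameSequence:
    """Time-ordered paired visible/thermal rasters with calibration.

    Frames are held either in memory (lists of arrays) or as file paths
    loaded lazily on access.  A missing frame may be ``None``; curve
    assembly interpolates short gaps.
    """

    def __init__(self, times_min, calibration: ThermalCalibration,
                 transform: AffineTransform,
                 visible_frames=None, thermal_frames=None,
                 visible_paths=None, thermal_paths=None,
                 saturation_count: int = 0,
                 temperature_frames: bool = False):
        self.times_min = np.asarray(times_min, dtype=float)
        if self.times_min.ndim != 1 or np.any(np.diff(self.times_min) <= 0):
            raise ValueError("frame times must be strictly increasing")
        self.calibration = calibration
        self.transform = transform
        self._visible = visible_frames
        self._thermal = thermal_frames
        self.visible_paths = visible_paths
        self.thermal_paths = thermal_paths
        self.saturation_count = saturation_count
        # True when thermal rasters already hold degC values (raw
        # temperature exports), bypassing the gray calibration
        self.temperature_frames = temperature_frames
        n = self.times_min.size
        for name, seq in (("visible", visible_frames or visible_paths),
                          ("thermal", thermal_frames or thermal_paths)):
            if seq is None or len(seq) != n:
                raise ValueError(f"{name} frames must match the {n} time points")

    def __len__(self) -> int:
        return self.times_min.size

    @property
    def interval_min(self) -> float:
        return float(self.times_min[1] - self.times_min[0])

    def _load(self, stored, paths, index, gray):
        if stored is not None:
            frame = stored[index]
        else:
            path = paths[index]
            if path is None:
                return None
            import imageio.v3 as iio

            frame = iio.imread(path)
        if frame is None:
            return None
        return _to_grayscale(frame) if gray else frame

    def visible(self, index: int) -> np.ndarray | None:
        """Visible frame as 2-D luminance array."""
        return self._load(self._visible, self.visible_paths, index, gray=True)

    def thermal(self, index: int) -> np.ndarray | None:
        return self._load(self._thermal, self.thermal_paths, index, gray=False)

    @property
    def visible_shape(self):
        return self.visible(0).shape

    @property
    def thermal_shape(self):
        return self.thermal(0).shape

    @classmethod
    def from_manifest(cls, manifest_path) -> "FrameSequence":
        """Load a sequence from a manifest CSV.

        Required columns: frame_index, time_min, visible_path,
        thermal_path, t_min_c, t_max_c.  Optional transform columns
        (scale_row, scale_col, offset_row, offset_col) default to pure
        scaling between the two raster shapes.  An optional boolean
        ``temperature_raster`` column marks thermal files that already
        hold degC values (e.g. float TIFF exports), which bypasses the
        gray calibration.
        """
        manifest_path = Path(manifest_path)
        df = pd.read_csv(manifest_path).sort_values("frame_index")
        base = manifest_path.parent
        vis = [str(base / p) for p in df["visible_path"]]
        thr = [str(base / p) for p in df["thermal_path"]]
        cal = ThermalCalibration(float(df["t_min_c"].iloc[0]),
                                 float(df["t_max_c"].iloc[0]))
        temp_raster = bool(df["temperature_raster"].iloc[0]) \
            if "temperature_raster" in df.columns else False
        seq = cls(df["time_min"].to_numpy(float), cal,
                  AffineTransform(), visible_paths=vis, thermal_paths=thr,
                  temperature_frames=temp_raster)
        if "scale_row" in df.columns:
            seq.transform = AffineTransform(
                float(df["scale_row"].iloc[0]), float(df["scale_col"].iloc[0]),
                float(df.get("offset_row", pd.Series([0.0])).iloc[0]),
                float(df.get("offset_col", pd.Series([0.0])).iloc[0]))
        else:
            seq.transform = AffineTransform.between(seq.visible_shape,
                                                    seq.thermal_shape)
        return seq


@dataclass
class SeedRegion:
    """Per-seed masks in visible space plus their thermal-space images."""

    seed_id: int
    mask: np.ndarray
    area_px: int
    centroid: tuple[float, float]
    disk: np.ndarray | None = None
    annulus: np.ndarray | None = None
    thermal_disk: np.ndarray | None = None
    thermal_annulus: np.ndarray | None = None


@dataclass
class SegmentationParams:
    """Tunables of the edge-extraction + region-growing segmenter.

    ``background_radius_px`` must exceed the seed radius (the grey
    opening keeps only structures wider than the window, i.e. the
    illumination field); ``blob_radius_px`` sits between the size of
    specular reflection points and the seed size, so the second opening
    suppresses reflections while leaving seeds intact.
    """

    background_radius_px: int = 30
    blob_radius_px: int = 4
    smooth_sigma: float = 1.5
    canny_sigma: float = 2.0
    canny_low: float = 4.0
    canny_high: float = 10.0
    closing_radius: int = 1
    region_dilation_px: int = 2
    marker_min_distance: int = 10
    marker_threshold: float = 25.0
    flood_tolerance: float = 55.0
    min_area_px: int = 100
    max_area_px: int = 10000

    @classmethod
    def for_seed_radius(cls, radius_px: float, **overrides) -> "SegmentationParams":
        """Defaults scaled to an expected seed radius in visible pixels."""
        area = np.pi * radius_px ** 2
        params = cls(
            background_radius_px=int(np.ceil(2.5 * radius_px)),
            marker_min_distance=max(3, int(radius_px)),
            min_area_px=max(9, int(0.3 * area)),
            max_area_px=int(1.8 * area),
        )
        for key, val in overrides.items():
            setattr(params, key, val)
        return params


def subtract_background(raster: np.ndarray,
                        background: np.ndarray | None = None,
                        *,
                        method: str = "morphology",
                        background_radius_px: int = 30,
                        blob_radius_px: int = 0,
                        percentile: float = 10.0) -> np.ndarray:
    """Remove the illumination field (and optionally reflection points).

    With an explicit ``background`` model the result is the clipped
    difference.  Otherwise the model is estimated from the frame itself:
    a grey opening (``method='morphology'``) or a running low percentile
    (``method='percentile'``) over a window wider than any seed, which
    follows smooth brightness gradients but not compact bright objects.
    A second, small grey opening (``blob_radius_px > 0``) then knocks
    out bright features narrower than a seed — specular reflection
    points on the wet filter paper.

    The output is non-negative; a constant raster minus its own model
    is identically zero.
    """
    img = _to_grayscale(raster).astype(float)
    if background is not None:
        background = _to_grayscale(background).astype(float)
        if background.shape != img.shape:
            raise ValueError(
                f"background shape {background.shape} != raster shape {img.shape}"
            )
        model = background
    elif method == "morphology":
        size = 2 * int(background_radius_px) + 1
        model = ndi.grey_opening(img, size=(size, size))
    elif method == "percentile":
        size = 2 * int(background_radius_px) + 1
        model = ndi.percentile_filter(img, percentile, size=size)
    else:
        raise ValueError(f"unknown background method {method!r}")
    corrected = np.clip(img - model, 0.0, None)
    if blob_radius_px > 0:
        size = 2 * int(blob_radius_px) + 1
        corrected = ndi.grey_opening(corrected, size=(size, size))
    return corrected


def segment_seeds(corrected: np.ndarray,
                  params: SegmentationParams | None = None) -> list[SeedRegion]:
    """Segment individual seeds from a background-corrected frame.

    Pipeline: Canny edge extraction (gradient magnitude + hysteresis),
    morphological closing of the edge map, then region growing by
    flood fill seeded at interior brightness maxima with an
    intensity-homogeneity tolerance; edges act as growth barriers.
    Regions outside the [min_area, max_area] gate are discarded (so two
    seeds merged across a touching bridge are excluded rather than
    accepted as one), and survivors are sorted row-major by centroid
    and given stable ids.

    Returns an empty list (with a warning log) when nothing is found.
    """
    if params is None:
        params = SegmentationParams()
    img = np.asarray(corrected, dtype=float)
    smoothed = ndi.gaussian_filter(img, params.smooth_sigma)

    edges = skfeature.canny(img, sigma=params.canny_sigma,
                            low_threshold=params.canny_low,
                            high_threshold=params.canny_high)
    if params.closing_radius > 0:
        edges = ndi.binary_closing(
            edges, structure=skmorph.disk(params.closing_radius))

    markers = skfeature.peak_local_max(
        smoothed, min_distance=params.marker_min_distance,
        threshold_abs=params.marker_threshold, exclude_border=False)
    if markers.size == 0:
        logger.warning("segment_seeds: no interior maxima found; empty scene?")
        return []

    # growth substrate: edge pixels forced far below any seed intensity
    barrier = smoothed.copy()
    barrier[edges] = -10.0 * params.flood_tolerance

    labels = np.zeros(img.shape, dtype=np.int32)
    order = np.argsort(-smoothed[markers[:, 0], markers[:, 1]])
    next_label = 0
    for r, c in markers[order]:
        if labels[r, c] != 0 or edges[r, c]:
            continue
        region = flood(barrier, (int(r), int(c)),
                       tolerance=params.flood_tolerance)
        region &= labels == 0
        region = ndi.binary_fill_holes(region)
        if params.region_dilation_px > 0:
            # recover the boundary ring withheld by the edge barrier
            region = ndi.binary_dilation(
                region, structure=skmorph.disk(params.region_dilation_px))
            region &= labels == 0
            region = ndi.binary_fill_holes(region)
        area = int(region.sum())
        if area < params.min_area_px or area > params.max_area_px:
            logger.info("segment_seeds: region at (%d, %d) rejected by area "
                        "gate (%d px)", r, c, area)
            labels[region] = -1  # claimed but not accepted
            continue
        next_label += 1
        labels[region] = next_label

    regions = []
    for lab in range(1, next_label + 1):
        mask = labels == lab
        area = int(mask.sum())
        cr, cc = ndi.center_of_mass(mask)
        regions.append(SeedRegion(seed_id=-1, mask=mask, area_px=area,
                                  centroid=(float(cr), float(cc))))
    regions.sort(key=lambda reg: (reg.centroid[0], reg.centroid[1]))
    for i, reg in enumerate(regions):
        reg.seed_id = i
    if not regions:
        logger.warning("segment_seeds: no regions passed the area gate")
    return regions


def _distance_sq_grid(shape, center):
    rr = np.arange(shape[0], dtype=float)[:, None] - center[0]
    cc = np.arange(shape[1], dtype=float)[None, :] - center[1]
    return rr ** 2 + cc ** 2


def make_disk(mask: np.ndarray, seed_id: int | str = "?") -> np.ndarray:
    """Central measurement disk of about one third of the mask area.

    The disk is centered on the mask centroid with radius
    ``sqrt(area / (3*pi))`` so its area is area/3; only pixels inside
    the full mask are retained.
    """
    mask = np.asarray(mask, dtype=bool)
    area = int(mask.sum())
    if area == 0:
        raise ValueError(f"seed {seed_id}: empty mask")
    center = ndi.center_of_mass(mask)
    radius = np.sqrt(area / (3.0 * np.pi))
    disk = _distance_sq_grid(mask.shape, center) <= radius ** 2
    disk &= mask
    count = int(disk.sum())
    if count == 0:
        raise ValueError(
            f"seed {seed_id}: central disk falls entirely outside the mask "
            "(centroid outside a non-convex region?)"
        )
    target = area / 3.0
    if area > 30 and abs(count - target) > 0.15 * target:
        logger.warning("seed %s: disk holds %d px, expected ~%.0f "
                       "(irregular mask shape)", seed_id, count, target)
    return disk


def make_annulus(mask: np.ndarray, all_masks: np.ndarray,
                 inner_scale: float = 1.2, outer_scale: float = 1.6,
                 seed_id: int | str = "?") -> np.ndarray:
    """Filter-paper environment ring around one seed.

    The ring spans ``inner_scale * r_eq`` to ``outer_scale * r_eq``
    around the mask centroid, where ``r_eq = sqrt(area/pi)`` is the
    equivalent circular radius, minus every seed mask so neighbouring
    seeds never leak into the environment estimate.
    """
    if not outer_scale > inner_scale >= 1.0:
        raise ValueError(
            f"require outer_scale > inner_scale >= 1, got "
            f"({inner_scale}, {outer_scale})"
        )
    mask = np.asarray(mask, dtype=bool)
    area = int(mask.sum())
    if area == 0:
        raise ValueError(f"seed {seed_id}: empty mask")
    center = ndi.center_of_mass(mask)
    r_eq = np.sqrt(area / np.pi)
    d2 = _distance_sq_grid(mask.shape, center)
    ring = (d2 >= (inner_scale * r_eq) ** 2) & (d2 <= (outer_scale * r_eq) ** 2)
    ring &= ~np.asarray(all_masks, dtype=bool)
    if not ring.any():
        raise LayoutError(
            f"seed {seed_id}: annulus empty after excluding seed masks; "
            "try a larger outer_scale"
        )
    return ring


def map_to_thermal(mask: np.ndarray, transform: AffineTransform,
                   thermal_shape, seed_id: int | str = "?") -> np.ndarray:
    """Carry a visible-space mask into thermal pixel coordinates.

    Each visible pixel center is mapped through the affine transform
    and rounded to the nearest thermal pixel; duplicates collapse.
    """
    rows, cols = np.nonzero(np.asarray(mask, dtype=bool))
    if rows.size == 0:
        raise ValueError(f"seed {seed_id}: empty mask")
    tr, tc = transform.apply(rows, cols)
    ri = np.rint(tr).astype(int)
    ci = np.rint(tc).astype(int)
    if (ri.min() < 0 or ci.min() < 0 or ri.max() >= thermal_shape[0]
            or ci.max() >= thermal_shape[1]):
        raise LayoutError(
            f"seed {seed_id}: mask maps outside the thermal raster "
            f"{tuple(thermal_shape)}"
        )
    out = np.zeros(thermal_shape, dtype=bool)
    out[ri, ci] = True
    return out


def build_regions(corrected: np.ndarray,
                  transform: AffineTransform,
                  thermal_shape,
                  params: SegmentationParams | None = None,
                  inner_scale: float = 1.2,
                  outer_scale: float = 1.6) -> list[SeedRegion]:
    """Segment a corrected frame and attach disk/annulus/thermal masks."""
    regions = segment_seeds(corrected, params)
    if not regions:
        return regions
    all_masks = np.zeros(corrected.shape[:2], dtype=bool)
    for reg in regions:
        all_masks |= reg.mask
    for reg in regions:
        reg.disk = make_disk(reg.mask, reg.seed_id)
        reg.annulus = make_annulus(reg.mask, all_masks, inner_scale,
                                   outer_scale, reg.seed_id)
        reg.thermal_disk = map_to_thermal(reg.disk, transform, thermal_shape,
                                          reg.seed_id)
        reg.thermal_annulus = map_to_thermal(reg.annulus, transform,
                                             thermal_shape, reg.seed_id)
    return regions
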