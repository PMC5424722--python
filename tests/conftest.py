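"""Shared fixtures: small phantom scenes rendered once per session."""

from __future__ import annotations

import numpy as np
import pytest

from thermoseed import features, imaging, phantom, thermo


def small_scene(**overrides) -> phantom.SceneConfig:
    """3x2 tray, 6-hour sequence, scaled-down rasters; noise-free."""
    defaults = dict(
        grid_rows=3, grid_cols=2, seed_radius_px=14.0,
        visible_size=(300, 450), thermal_size=(120, 180),
        duration_min=360.0, noise_sd_gray=0.0, texture_sd_gray=0.0,
        rng_seed=11,
    )
    defaults.update(overrides)
    return phantom.SceneConfig(**defaults)


@pytest.fixture(scope="session")
def clean_scene() -> phantom.SceneConfig:
    return small_scene()


@pytest.fixture(scope="session")
def clean_cohort(clean_scene):
    rng = np.random.default_rng(clean_scene.rng_seed)
    return phantom.make_labelled_cohort(2, 2, 2, clean_scene, rng=rng)


@pytest.fixture(scope="session")
def clean_sequence(clean_scene, clean_cohort):
    return phantom.render_sequence(clean_scene, clean_cohort)


@pytest.fixture(scope="session")
def clean_regions(clean_scene, clean_sequence):
    params = imaging.SegmentationParams.for_seed_radius(
        clean_scene.seed_radius_px)
    corrected = imaging.subtract_background(
        clean_sequence.visible(0),
        background_radius_px=params.background_radius_px,
        blob_radius_px=params.blob_radius_px)
    return imaging.build_regions(corrected, clean_sequence.transform,
                                 clean_scene.thermal_size, params)


def match_region(region, truths):
    """Ground-truth seed nearest to a segmented region's centroid."""
    dists = [np.hypot(region.centroid[0] - t.center_visible[0],
                      region.centroid[1] - t.center_visible[1])
             for t in truths]
    return truths[int(np.argmin(dists))]


@pytest.fixture(scope="session")
def cohort_features():
    """120-seed curves-only cohort: feature table, early table, labels."""
    cfg = phantom.SceneConfig(grid_rows=12, grid_cols=10, seed_radius_px=12.0,
                              rng_seed=7)
    rng = np.random.default_rng(7)
    truths = phantom.make_labelled_cohort(41, 32, 47, cfg, rng=rng)
    curves = [thermo.TemperatureCurve(seed_id=t.seed_id,
                                      times_min=cfg.times_min, r_t=t.curve)
              for t in truths]
    table = features.features_table(curves)
    early = features.early_vector_table(curves)
    labels = np.array([t.viability_class for t in truths])
    return table, early, labels, truths
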