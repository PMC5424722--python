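"""Phantom generator: curve grammar, cohort labels, rendering physics."""

import numpy as np
import pytest

from thermoseed import phantom, thermo
from thermoseed.imaging import LayoutError
from thermoseed.phantom import CurveTemplate, SceneConfig, sample_curve

from conftest import small_scene


class TestSampleCurve:
    def test_flat_zero_template_gives_zero_series(self):
        tmpl = CurveTemplate(viability_class="viable", t_peak_min=10,
                             t_drop_min=20, t_min_min=30, rebound_c=0.0)
        series = sample_curve(tmpl, 360.0, 5.0, np.random.default_rng(0))
        assert np.allclose(series, 0.0)

    def test_minimum_forced_at_landmark(self):
        tmpl = CurveTemplate(viability_class="viable", rt_start_c=0.0,
                             rt_peak_c=0.05, rt_min_c=-1.0, plateau_c=-0.8,
                             t_peak_min=20, t_drop_min=100, t_min_min=240,
                             rebound_c=0.3)
        series = sample_curve(tmpl, 720.0, 5.0, np.random.default_rng(0))
        t = np.arange(series.size) * 5.0
        assert series.min() == pytest.approx(-1.0)
        assert t[np.argmin(series)] == pytest.approx(240.0)

    def test_jittered_minima_unbiased(self):
        # Monte-Carlo: mean of realized minima within 3 SE of the landmark
        tmpl = CurveTemplate(viability_class="viable", rt_min_c=-1.0,
                             plateau_c=-0.8, t_peak_min=20, t_drop_min=100,
                             t_min_min=240, rebound_c=0.3, sd_rt_min=0.05)
        rng = np.random.default_rng(42)
        minima = [sample_curve(tmpl, 360.0, 5.0, rng).min()
                  for _ in range(200)]
        se = 0.05 / np.sqrt(200)
        assert abs(np.mean(minima) - (-1.0)) < 3 * se

    def test_inconsistent_timing_rejected(self):
        tmpl = CurveTemplate(viability_class="viable", t_peak_min=100,
                             t_drop_min=50, t_min_min=200)
        with pytest.raises(ValueError, match="timing"):
            sample_curve(tmpl, 360.0, 5.0, np.random.default_rng(0))

    def test_min_above_start_rejected(self):
        tmpl = CurveTemplate(viability_class="viable", rt_start_c=-1.0,
                             rt_min_c=0.5, t_peak_min=10, t_drop_min=20,
                             t_min_min=30)
        with pytest.raises(ValueError, match="rt_min"):
            sample_curve(tmpl, 360.0, 5.0, np.random.default_rng(0))


class TestCohort:
    def test_class_counts_and_root_length_bands(self):
        cfg = SceneConfig(grid_rows=6, grid_cols=5, rng_seed=1)
        truths = phantom.make_labelled_cohort(10, 10, 10, cfg,
                                              rng=np.random.default_rng(1))
        assert len(truths) == 30
        for t in truths:
            lo, hi = phantom.ROOT_LENGTH_BANDS[t.viability_class]
            assert lo <= t.root_length_cm <= hi
        counts = {c: sum(t.viability_class == c for t in truths)
                  for c in ("viable", "aged", "non_viable")}
        assert counts == {"viable": 10, "aged": 10, "non_viable": 10}

    def test_single_nonviable_seed(self):
        cfg = small_scene()
        truths = phantom.make_labelled_cohort(0, 0, 1, cfg,
                                              rng=np.random.default_rng(0))
        assert len(truths) == 1
        assert truths[0].viability_class == "non_viable"
        assert truths[0].root_length_cm == 0.0

    def test_capacity_enforced(self):
        cfg = small_scene()  # 3x2 tray
        with pytest.raises(LayoutError, match="capacity"):
            phantom.make_labelled_cohort(4, 2, 2, cfg,
                                         rng=np.random.default_rng(0))


class TestRender:
    def test_ambient_quantizes_to_midspan_gray(self):
        # ambient 24 degC in the 21-27 window -> gray round(255*3/6) = 128
        cfg = small_scene(ambient_drift_c=0.0)
        truths = phantom.make_labelled_cohort(0, 0, 1, cfg,
                                              rng=np.random.default_rng(0))
        truths[0].curve[:] = 0.0
        seq = phantom.render_sequence(cfg, truths)
        frame = seq.thermal(0)
        assert np.all(frame[truths[0].thermal_mask] == 128)
        assert np.all(frame == 128)  # rT=0 everywhere at zero drift/noise

    def test_empty_scene_is_pure_background(self):
        cfg = small_scene()
        seq = phantom.render_sequence(cfg, [])
        vis = seq.visible(0)
        assert np.all(vis == cfg.background_gray)

    def test_determinism_bit_identical(self):
        cfg = small_scene(noise_sd_gray=1.0, texture_sd_gray=4.0)
        out = []
        for _ in range(2):
            rng = np.random.default_rng(cfg.rng_seed)
            truths = phantom.make_labelled_cohort(2, 2, 2, cfg, rng=rng)
            seq = phantom.render_sequence(cfg, truths)
            out.append((truths, seq))
        (t1, s1), (t2, s2) = out
        assert all(a.root_length_cm == b.root_length_cm
                   and np.array_equal(a.curve, b.curve)
                   for a, b in zip(t1, t2))
        for i in (0, len(s1) - 1):
            assert np.array_equal(s1.visible(i), s2.visible(i))
            assert np.array_equal(s1.thermal(i), s2.thermal(i))

    def test_overlapping_seeds_rejected(self):
        cfg = small_scene()
        rng = np.random.default_rng(0)
        truths = phantom.make_labelled_cohort(2, 0, 0, cfg, rng=rng)
        truths[1].visible_mask = truths[0].visible_mask.copy()
        with pytest.raises(LayoutError, match="overlap"):
            phantom.render_sequence(cfg, truths)

    def test_out_of_window_temperatures_logged_as_saturated(self):
        cfg = small_scene(ambient_c=26.9)  # seed cooling dives below Tmin? no:
        # ambient near Tmax so the early positive peak exceeds 27 degC
        truths = phantom.make_labelled_cohort(0, 1, 0, cfg,
                                              rng=np.random.default_rng(0))
        seq = phantom.render_sequence(cfg, truths)
        assert seq.saturation_count > 0

    def test_footprint_mean_recovers_curve_within_half_step(self, clean_scene,
                                                            clean_cohort,
                                                            clean_sequence):
        # decode through the calibration using the true thermal footprints
        cal = clean_scene.calibration
        drift = clean_scene.ambient_drift_c * np.sin(
            2 * np.pi * clean_sequence.times_min / clean_scene.drift_period_min)
        for truth in clean_cohort:
            for i in (0, 20, 50):
                frame = clean_sequence.thermal(i)
                t_seed = thermo.region_mean_temperature(
                    frame, truth.thermal_mask, cal)
                expected = clean_scene.ambient_c + drift[i] + truth.curve[i]
                assert abs(t_seed - expected) <= cal.step_c / 2 + 1e-9

    def test_manifest_round_trip(self, tmp_path):
        from thermoseed.imaging import FrameSequence

        cfg = small_scene(duration_min=15.0)
        quick = {
            cls: phantom.CurveTemplate(viability_class=cls, rt_min_c=-0.5,
                                       t_peak_min=0, t_drop_min=5,
                                       t_min_min=10, rebound_c=0.2)
            for cls in ("viable", "aged", "non_viable")
        }
        truths = phantom.make_labelled_cohort(1, 1, 1, cfg, templates=quick,
                                              rng=np.random.default_rng(2))
        seq = phantom.render_sequence(cfg, truths, out_dir=tmp_path)
        loaded = FrameSequence.from_manifest(tmp_path / "manifest.csv")
        assert len(loaded) == cfg.n_frames
        assert loaded.calibration == cfg.calibration
        assert loaded.transform == cfg.transform
        assert np.array_equal(loaded.thermal(1), seq.thermal(1))
        assert np.array_equal(loaded.visible(1), seq.visible(1))


def test_default_templates_satisfy_shape_grammar():
    for tmpl in phantom.DEFAULT_TEMPLATES.values():
        tmpl.validate(7200.0)
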