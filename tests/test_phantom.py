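"""Phantom module: flow evaluation, advection, rendering, cine generation."""

import numpy as np
import pytest

from conftest import analytic_cine, make_cloud, steady
from speckleflow.errors import DomainError, ParameterError, ValidationError
from speckleflow.phantom import (
    FlowModel,
    ImagingConfig,
    ScattererCloud,
    advect,
    evaluate_flow,
    generate_cine,
    postop_like_flow,
    preop_like_flow,
    render_frame,
    seed_cloud,
    systolic_waveform,
)


class TestWaveform:
    def test_envelope_shape(self):
        assert systolic_waveform(0.2) == pytest.approx(1.0)
        assert systolic_waveform(0.0) == 0.0
        assert systolic_waveform(0.7) == 0.0
        s = np.linspace(0, 0.999, 500)
        w = systolic_waveform(s)
        assert np.all((w >= 0) & (w <= 1))
        assert np.argmax(w) == np.argmin(np.abs(s - 0.2))

    def test_periodicity(self):
        s = np.linspace(0, 1, 37, endpoint=False)
        np.testing.assert_allclose(
            systolic_waveform(s), systolic_waveform(s + 3.0), atol=1e-12
        )


class TestEvaluateFlow:
    def test_uniform_field_constant(self):
        model = FlowModel(kind="uniform", peak_speed=1.0, waveform=steady)
        v = evaluate_flow(model, 3.0, 7.0, 0.123, 1.0)
        np.testing.assert_allclose(v, [1.0, 0.0])
        grid = evaluate_flow(
            model, np.linspace(0, 8, 9), np.linspace(0, 8, 9), 0.5, 1.0
        )
        np.testing.assert_allclose(grid[..., 0], 1.0)

    @pytest.mark.parametrize(
        "model",
        [
            FlowModel(kind="uniform"),
            FlowModel(kind="parabolic"),
            postop_like_flow(),
            preop_like_flow(),
        ],
        ids=["uniform", "parabolic", "tophat", "stenotic"],
    )
    def test_waveform_zero_gives_rest(self, model):
        v = model.evaluate(4.0, np.linspace(0, 10, 21), 0.7, 1.0)
        np.testing.assert_allclose(v, 0.0, atol=1e-14)

    def test_stenotic_recirculation_negative_at_peak_systole(self):
        model = preop_like_flow()
        y_band = np.linspace(8.0, 9.5, 10)
        v = model.evaluate(4.0, y_band, 0.2, 1.0)
        assert np.all(v[..., 0] < 0)

    def test_stenotic_sign_change_across_shear_layer(self):
        model = preop_like_flow()
        y = np.linspace(0.5, 10.0, 200)
        vx = model.evaluate(4.0, y, 0.2, 1.0)[..., 0]
        assert vx.max() > 0 and vx.min() < 0

    def test_stenotic_peak_speed_at_peak_systole(self):
        model = preop_like_flow()
        y = np.linspace(0.0, 10.4, 500)
        vx = model.evaluate(4.0, y, 0.2, 1.0)[..., 0]
        assert vx.max() == pytest.approx(model.peak_speed, rel=1e-3)

    def test_out_of_domain_raises(self):
        model = FlowModel(kind="uniform", fov=(8.0, 8.0))
        with pytest.raises(DomainError):
            model.evaluate(9.0, 2.0, 0.1, 1.0)
        with pytest.raises(ParameterError):
            model.evaluate(1.0, 2.0, 0.1, -1.0)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValidationError):
            FlowModel(kind="vortex")


class TestAdvect:
    def test_uniform_displacement_one_frame(self, imaging_small):
        # 1.0 m/s for 1/6000 s is 1/6 mm
        model = FlowModel(kind="uniform", peak_speed=1.0, waveform=steady)
        cloud = make_cloud(imaging_small)
        rng = np.random.default_rng(1)
        moved = advect(cloud, model, 0.0, 1.0 / 6000.0, 1.0, rng)
        dx = moved.positions[:, 0] - cloud.positions[:, 0]
        inside = moved.positions[:, 0] > cloud.positions[:, 0]  # not wrapped
        np.testing.assert_allclose(dx[inside], 1000.0 / 6000.0, rtol=1e-12)

    def test_zero_flow_is_identity(self, imaging_small):
        model = FlowModel(kind="uniform", peak_speed=0.0)
        cloud = make_cloud(imaging_small)
        moved = advect(cloud, model, 0.0, 1e-4, 1.0, np.random.default_rng(0))
        np.testing.assert_array_equal(moved.positions, cloud.positions)

    def test_count_conserved_with_reseeding(self, imaging_small):
        model = FlowModel(kind="uniform", peak_speed=2.0, waveform=steady)
        cloud = make_cloud(imaging_small)
        rng = np.random.default_rng(2)
        for k in range(30):
            cloud = advect(cloud, model, k * 1e-3, 1e-3, 1.0, rng)
        assert len(cloud) == len(make_cloud(imaging_small))
        x0, x1, y0, y1 = cloud.bounds
        assert np.all((cloud.positions[:, 0] >= x0) & (cloud.positions[:, 0] <= x1))

    def test_bad_dt_rejected(self, imaging_small):
        cloud = make_cloud(imaging_small)
        with pytest.raises(ParameterError):
            advect(cloud, FlowModel(), 0.0, 0.0, 1.0, np.random.default_rng(0))


class TestRender:
    def test_single_scatterer_peaks_at_its_pixel(self):
        cfg = ImagingConfig(n_x=32, n_y=32, noise_sigma=0.0)
        pos = np.array([[20 * cfg.pixel_pitch, 11 * cfg.pixel_pitch]])
        cloud = ScattererCloud(pos, np.array([1.0]), (0, 32, 0, 32), 1.0)
        img = render_frame(cloud, cfg, seed=0)
        assert np.unravel_index(np.argmax(img), img.shape) == (11, 20)

    def test_deterministic_for_fixed_seed(self, imaging_small):
        cfg = ImagingConfig(n_x=64, n_y=64, noise_sigma=0.05)
        cloud = make_cloud(cfg)
        a = render_frame(cloud, cfg, seed=42)
        b = render_frame(cloud, cfg, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_integer_shift_equivariance(self):
        cfg = ImagingConfig(n_x=64, n_y=64, noise_sigma=0.0)
        cloud = make_cloud(cfg, seed=3)
        img = render_frame(cloud, cfg, seed=0)
        k = 3
        shifted_cloud = ScattererCloud(
            cloud.positions + np.array([k * cfg.pixel_pitch, 0.0]),
            cloud.reflectivities, cloud.bounds, cloud.density,
        )
        img_s = render_frame(shifted_cloud, cfg, seed=0)
        interior = np.s_[:, 10:-10]
        np.testing.assert_allclose(
            img_s[:, 10 + k : -10 + k], img[interior],
            atol=1e-6 * img.max(),
        )

    def test_empty_cloud_rejected(self, imaging_small):
        cloud = ScattererCloud(
            np.empty((0, 2)), np.empty(0), (0, 1, 0, 1), 1.0
        )
        with pytest.raises(ValidationError):
            render_frame(cloud, imaging_small, seed=0)

    def test_speckle_fully_developed(self):
        # default scatterer density leaves no blank 8x8 tiles
        cfg = ImagingConfig(n_x=96, n_y=96, noise_sigma=0.0)
        img = render_frame(make_cloud(cfg, seed=7), cfg, seed=1)
        tiles = img[: 96 - 96 % 8, :].reshape(12, 8, 12, 8).transpose(0, 2, 1, 3)
        variances = tiles.reshape(144, 64).var(axis=1)
        assert np.mean(variances > 0) >= 0.99


class TestGenerateCine:
    def test_counts_metadata_and_truth(self):
        cfg = ImagingConfig(n_x=48, n_y=48, frames_per_cycle=8, n_cycles=2,
                            noise_sigma=0.0)
        model = preop_like_flow()
        cine, truth = generate_cine(model, cfg, seed=0)
        assert cine.n_frames == 16 and truth.shape == (16, 48, 48, 2)
        assert cine.meta.pixel_pitch == cfg.pixel_pitch
        assert cine.meta.prf == cfg.prf
        assert cine.meta.period == pytest.approx(8 / 6000.0)
        # ground-truth stack equals direct flow evaluation on the grid
        xs = np.arange(48) * cfg.pixel_pitch
        ys = np.arange(48) * cfg.pixel_pitch
        gx, gy = np.meshgrid(xs, ys)
        k = 5
        expect = model.evaluate(gx, gy, cine.meta.frame_times[k], cfg.period,
                                check_domain=False)
        np.testing.assert_array_equal(truth[k], expect)

    def test_zero_flow_gives_static_noiseless_frames(self):
        cfg = ImagingConfig(n_x=48, n_y=48, frames_per_cycle=4, noise_sigma=0.0)
        model = FlowModel(kind="uniform", peak_speed=0.0)
        cine, truth = generate_cine(model, cfg, seed=1)
        np.testing.assert_array_equal(truth, 0.0)
        for k in range(1, cine.n_frames):
            np.testing.assert_array_equal(cine.tissue[k], cine.tissue[0])

    def test_truth_peak_matches_envelope(self):
        cfg = ImagingConfig(n_x=48, n_y=128, frames_per_cycle=10, noise_sigma=0.0)
        model = preop_like_flow()
        cine, truth = generate_cine(model, cfg, seed=2)
        k = 2  # phase 0.2 exactly
        # tolerance covers the pixel-grid sampling of the jet-core maximum
        assert truth[k, ..., 0].max() == pytest.approx(
            model.peak_speed * systolic_waveform(0.2), rel=2e-3
        )
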