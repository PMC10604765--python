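"""Shear profiles, TAWSS/OSI quadrature, wall series and Bernoulli."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import analytic_cine, steady
from speckleflow.errors import (
    InsufficientDataError,
    ParameterError,
    QualityError,
)
from speckleflow.fields import LineProfile
from speckleflow.hemodynamics import (
    WSSSeries,
    bernoulli_gradient,
    ensemble_wall_series,
    indicators,
    osi,
    peak_velocity_trace,
    shear_profile,
    tawss,
    wall_series,
)
from speckleflow.phantom import (
    FlowModel,
    ImagingConfig,
    postop_like_flow,
    preop_like_flow,
)


def sine_series(amplitude=1.0, offset=0.0, n=1000, period=0.8):
    t = np.linspace(0.0, period, n)
    return WSSSeries(t, offset + amplitude * np.sin(2 * np.pi * t / period))


def random_series(rng, n=64, period=0.8):
    """Random admissible WSS series: offset plus a few harmonics."""
    t = np.linspace(0.0, period, n)
    w = rng.normal(0, 0.5) * np.ones(n)
    for h in range(1, 4):
        w = w + rng.normal(0, 1.0) * np.sin(
            2 * np.pi * h * t / period + rng.uniform(0, 2 * np.pi)
        )
    return WSSSeries(t, w)


class TestShearProfile:
    def test_linear_profile_constant_stress(self):
        y = np.linspace(0, 5, 26)
        v = 0.1 * y  # 100 1/s gradient (0.1 m/s per mm)
        sp = shear_profile(v, y, mu=0.0035)
        np.testing.assert_allclose(sp.tau, 0.35, rtol=1e-9)

    def test_constant_profile_zero_stress(self):
        y = np.linspace(0, 5, 26)
        sp = shear_profile(np.full(26, 0.7), y)
        np.testing.assert_allclose(sp.tau, 0.0, atol=1e-12)

    def test_sine_profile_matches_analytic_derivative(self):
        k = 2 * np.pi / 4.0  # wavenumber, 1/mm (one wavelength over 4 mm)
        y = np.arange(0, 8.0, (2 * np.pi / k) / 50)
        v = np.sin(k * y)
        sp = shear_profile(v, y, mu=0.0035)
        expect = 0.0035 * k * 1e3  # mu * k converted to SI (k in 1/m)
        assert np.nanmax(np.abs(sp.tau)) == pytest.approx(expect, rel=0.02)

    def test_masked_gap_not_bridged(self):
        y = np.linspace(0, 5, 26)
        v = 0.1 * y
        mask = np.ones(26, bool)
        mask[10:13] = False
        sp = shear_profile(v, y, valid=mask)
        assert np.all(np.isnan(sp.tau[10:13]))
        assert np.all(np.isfinite(sp.tau[:10])) and np.all(np.isfinite(sp.tau[13:]))

    def test_too_few_valid_samples(self):
        with pytest.raises(InsufficientDataError):
            shear_profile(np.array([1.0, 2.0, 3.0, 4.0]),
                          np.linspace(0, 1, 4),
                          valid=np.array([True, True, False, False]))


class TestTawss:
    def test_constant_series(self):
        t = np.linspace(0, 0.8, 100)
        assert tawss(WSSSeries(t, np.full(100, -2.5))) == pytest.approx(2.5)

    def test_sine_series_two_over_pi(self):
        s = sine_series(amplitude=1.3)
        assert tawss(s) == pytest.approx(1.3 * 2 / np.pi, rel=0.005)

    def test_homogeneity(self):
        rng = np.random.default_rng(0)
        s = random_series(rng)
        doubled = WSSSeries(s.times, 2 * s.wss)
        assert tawss(doubled) == pytest.approx(2 * tawss(s), rel=1e-12)


class TestOsi:
    def test_always_positive_is_zero(self):
        s = sine_series(amplitude=0.5, offset=1.0)
        assert osi(s) == 0.0

    def test_pure_sine_is_half(self):
        assert osi(sine_series()) == pytest.approx(0.5, abs=1e-3)

    def test_half_net_integral_gives_quarter(self):
        # |net| equal to half the rectified integral: OSI = (1 - 1/2)/2
        t = np.linspace(0, 1.0, 4001)
        w = np.where(t % 1.0 < 0.5, 3.0, -1.0)
        s = WSSSeries(t, w)
        assert osi(s) == pytest.approx(0.25, abs=2e-3)

    def test_identically_zero_flagged(self):
        t = np.linspace(0, 0.8, 10)
        with pytest.raises(ParameterError):
            osi(WSSSeries(t, np.zeros(10)))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_bounds_for_random_series(self, seed):
        s = random_series(np.random.default_rng(seed))
        assert 0.0 <= osi(s) <= 0.5

    def test_sign_flip_invariance(self):
        s = random_series(np.random.default_rng(3))
        flipped = WSSSeries(s.times, -s.wss)
        assert osi(flipped) == pytest.approx(osi(s), abs=1e-12)
        assert tawss(flipped) == pytest.approx(tawss(s), rel=1e-12)

    def test_quadrature_convergence(self):
        # TAWSS of the sinusoid carries the trapezoid error of the
        # rectified integral and converges quadratically to 2A/pi; OSI of
        # the same series is exact at any n because the net integral
        # cancels by antisymmetry on the uniform grid
        target = 2 / np.pi
        errs = [abs(tawss(sine_series(n=n)) - target) for n in (33, 129, 513)]
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] < errs[0] / 50
        assert osi(sine_series(n=33)) == pytest.approx(0.5, abs=1e-12)


class TestIndicators:
    def test_steady_positive_series(self):
        t = np.linspace(0, 0.8, 50)
        ind = indicators(WSSSeries(t, np.full(50, 1.7)))
        assert ind.tawss == pytest.approx(1.7)
        assert ind.osi == 0.0

    def test_sine_series_bundle(self):
        ind = indicators(sine_series(amplitude=2.0))
        assert ind.tawss == pytest.approx(2.0 * 2 / np.pi, rel=0.005)
        assert ind.osi == pytest.approx(0.5, abs=1e-3)


class TestWallSeries:
    def poiseuille_cine(self):
        cfg = ImagingConfig(n_x=48, n_y=128, frames_per_cycle=8)
        model = FlowModel(kind="parabolic", peak_speed=1.0, jet_center_y=5.2,
                          jet_width=8.0, waveform=steady)
        return analytic_cine(model, cfg), cfg

    def test_steady_channel_flow_symmetric_walls(self):
        cine, cfg = self.poiseuille_cine()
        line = LineProfile((1.9, 1.4), (1.9, 9.0), n_samples=93)
        ant = wall_series(cine, line, "anterior")
        post = wall_series(cine, line, "posterior")
        assert np.ptp(ant.wss) == pytest.approx(0.0, abs=1e-12)
        # forward flow: positive WSS at both walls, symmetric magnitudes
        assert ant.wss[0] > 0 and post.wss[0] > 0
        assert ant.wss[0] == pytest.approx(post.wss[0], rel=0.05)

    def test_stenotic_posterior_sign_change_anterior_none(self):
        cfg = ImagingConfig(n_x=48, n_y=128, frames_per_cycle=25)
        cine = analytic_cine(preop_like_flow(), cfg)
        line = LineProfile((1.9, 1.24), (1.9, 9.16), n_samples=97)
        post = wall_series(cine, line, "posterior")
        ant = wall_series(cine, line, "anterior")
        assert post.wss.min() < 0 < post.wss.max()
        assert ant.wss.min() >= -1e-9

    def test_zero_confidence_is_quality_error(self):
        cine, cfg = self.poiseuille_cine()
        cine.confidence[:] = 0.0
        line = LineProfile((1.9, 1.4), (1.9, 9.0))
        with pytest.raises(QualityError):
            wall_series(cine, line, "posterior")

    def test_stenotic_osi_contrast_between_scenarios(self):
        # the pre-repair posterior wall oscillates; the post-repair one
        # does not: OSI(stenotic) >> OSI(top-hat) at the posterior wall
        cfg = ImagingConfig(n_x=48, n_y=128, frames_per_cycle=25)
        line = LineProfile((1.9, 1.24), (1.9, 9.16), n_samples=97)
        pre = indicators(wall_series(analytic_cine(preop_like_flow(), cfg),
                                     line, "posterior"))
        post = indicators(wall_series(analytic_cine(postop_like_flow(), cfg),
                                      line, "posterior"))
        assert pre.osi > 0.1 > post.osi
        assert post.osi < 0.05

    def test_ensemble_average_of_identical_lines(self):
        cine, cfg = self.poiseuille_cine()
        line = LineProfile((1.9, 1.4), (1.9, 9.0), n_samples=93)
        single = wall_series(cine, line, "anterior")
        ens = ensemble_wall_series(cine, [line, line], "anterior")
        np.testing.assert_allclose(ens.wss, single.wss)


class TestTraces:
    def test_uniform_flow_unit_trace(self):
        cfg = ImagingConfig(n_x=32, n_y=32, frames_per_cycle=4)
        cine = analytic_cine(FlowModel(kind="uniform", peak_speed=1.0,
                                       waveform=steady), cfg)
        line = LineProfile((1.3, 0.4), (1.3, 2.2))
        trace = peak_velocity_trace(cine, line)
        np.testing.assert_allclose(trace["v_peak_mps"], 1.0)
        np.testing.assert_allclose(trace["mean_confidence"], 1.0)

    def test_peak_occurs_at_systolic_phase(self):
        cfg = ImagingConfig(n_x=32, n_y=128, frames_per_cycle=20)
        cine = analytic_cine(preop_like_flow(), cfg)
        line = LineProfile((1.3, 1.0), (1.3, 10.0))
        trace = peak_velocity_trace(cine, line)
        best = trace.loc[trace["v_peak_mps"].idxmax(), "phase"]
        assert best == pytest.approx(0.2, abs=0.05)


class TestBernoulli:
    @pytest.mark.parametrize(
        "v,expected", [(3.5, 49.0), (0.0, 0.0), (1.4, 7.84)]
    )
    def test_simplified_gradient(self, v, expected):
        assert bernoulli_gradient(v) == pytest.approx(expected)

    def test_negative_velocity_rejected(self):
        with pytest.raises(ParameterError):
            bernoulli_gradient(-0.1)
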