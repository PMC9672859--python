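"""Forward-model tests: pure decays, IRF convolution, closed-form oracles."""
import itertools

import numpy as np
import pytest

from flimkit.decay_model import (
    CompositeDecayModel,
    ExpComponent,
    GaussianIrf,
    MeasuredIrf,
    convolve_irf,
    exp_mod_gauss,
    model_curve,
    pure_decay,
)
from flimkit.errors import GridMismatchError, InvalidGridError, InvalidParameterError
from flimkit.histogram import DecayHistogram, TimeGrid


def mono(amplitude, tau, irf=None):
    return CompositeDecayModel((ExpComponent(amplitude, tau),), irf=irf)


class TestPureDecay:
    def test_identity_at_origin(self):
        grid = TimeGrid(np.linspace(0.0, 3.5, 8))
        out = pure_decay(mono(1.0, 1.0), grid, t0=0.0)
        assert out[0] == pytest.approx(1.0)

    def test_analytic_value(self):
        grid = TimeGrid(np.linspace(0.0, 3.5, 8))
        out = pure_decay(mono(2.0, 2.0), grid, t0=0.0)
        assert out[grid.bin_centers.tolist().index(2.0)] == pytest.approx(2 * np.exp(-1))

    def test_two_components_sum_of_parts(self):
        """Bi-exponential equals independent per-component evaluation summed."""
        grid = TimeGrid(np.linspace(0.0, 3.5, 8))
        bi = CompositeDecayModel(
            (ExpComponent(1.0, 0.5), ExpComponent(1.0, 3.0)))
        out = pure_decay(bi, grid, t0=0.0)
        expected = (pure_decay(mono(1.0, 0.5), grid, t0=0.0)
                    + pure_decay(mono(1.0, 3.0), grid, t0=0.0))
        np.testing.assert_allclose(out, expected, rtol=1e-12)
        i = grid.bin_centers.tolist().index(1.0)
        assert out[i] == pytest.approx(np.exp(-2) + np.exp(-1 / 3))

    def test_zero_before_t0_and_decreasing_after(self):
        grid = TimeGrid.from_window(10.0, 100)
        out = pure_decay(mono(5.0, 1.5), grid, t0=3.0)
        t = grid.bin_centers
        assert np.all(out[t < 3.0] == 0)
        after = out[t >= 3.0]
        assert np.all(np.diff(after) < 0)

    def test_t0_outside_grid_raises(self):
        grid = TimeGrid.from_window(10.0, 100)
        with pytest.raises(InvalidParameterError):
            pure_decay(mono(1.0, 1.0), grid, t0=50.0)

    def test_invalid_lifetime_raises(self):
        with pytest.raises(InvalidParameterError):
            ExpComponent(1.0, -2.0)
        with pytest.raises(InvalidParameterError):
            ExpComponent(-1.0, 2.0)

    def test_nonuniform_grid_rejected(self):
        with pytest.raises(InvalidGridError):
            TimeGrid(np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 8.0]))


class TestConvolveIrf:
    def test_near_delta_kernel_is_identity(self):
        grid = TimeGrid.from_window(12.5, 250)
        decay = np.exp(-grid.bin_centers / 2.0)
        # delta centred on the first bin: mu at the first bin center
        irf = GaussianIrf(mu=float(grid.bin_centers[0]), sigma=grid.dt / 100)
        out = convolve_irf(decay, irf, grid)
        np.testing.assert_allclose(out, decay, rtol=1e-3)

    def test_matches_direct_nested_loop(self):
        """FFT path agrees with an O(N^2) direct convolution to 1e-9."""
        grid = TimeGrid.from_window(6.0, 120)
        rng = np.random.default_rng(7)
        decay = rng.random(grid.n_bins)
        irf = GaussianIrf(mu=1.0, sigma=0.2)
        out = convolve_irf(decay, irf, grid)
        z = (grid.bin_centers - 1.0) / 0.2
        kernel = np.exp(-0.5 * z * z)
        kernel /= kernel.sum()
        direct = np.zeros(grid.n_bins)
        for j in range(grid.n_bins):
            for k in range(j + 1):
                direct[j] += decay[k] * kernel[j - k]
        np.testing.assert_allclose(out, direct, rtol=1e-9, atol=1e-12)

    @pytest.mark.parametrize("tau,sigma", list(itertools.product(
        [0.3, 1.2, 4.0], [0.05, 0.3])))
    def test_matches_exponentially_modified_gaussian(self, tau, sigma):
        """Mono decay x Gaussian equals the closed-form EMG at fine binning."""
        mu = 10 * sigma
        dt = sigma / 200
        n = int(np.ceil((mu + 8 * tau) / dt))
        grid = TimeGrid((np.arange(n) + 0.5) * dt)
        curve = model_curve(mono(1.0, tau, GaussianIrf(mu, sigma)), grid)
        closed = exp_mod_gauss(grid.bin_centers, 1.0, tau, mu, sigma)
        mask = closed > closed.max() * 1e-4
        np.testing.assert_allclose(curve[mask], closed[mask], rtol=1e-4)

    def test_linearity(self):
        grid = TimeGrid.from_window(12.5, 250)
        rng = np.random.default_rng(3)
        x, y = rng.random(250), rng.random(250)
        irf = GaussianIrf(mu=2.0, sigma=0.3)
        lhs = convolve_irf(2.5 * x + 0.5 * y, irf, grid)
        rhs = 2.5 * convolve_irf(x, irf, grid) + 0.5 * convolve_irf(y, irf, grid)
        np.testing.assert_allclose(lhs, rhs, rtol=0, atol=1e-12 * lhs.max())

    def test_count_conservation_interior_irf(self):
        """Total counts preserved when decay and IRF mass are interior."""
        grid = TimeGrid.from_window(40.0, 800)
        decay = np.exp(-grid.bin_centers / 1.5)  # decayed to ~0 by the end
        irf = GaussianIrf(mu=2.0, sigma=0.2)
        out = convolve_irf(decay, irf, grid)
        assert abs(out.sum() - decay.sum()) / decay.sum() < 1e-6

    def test_measured_irf_equivalent_to_gaussian_histogram(self):
        grid = TimeGrid.from_window(12.5, 250)
        z = (grid.bin_centers - 1.5) / 0.15
        counts = np.exp(-0.5 * z * z)
        measured = MeasuredIrf(DecayHistogram(grid, counts))
        decay = np.exp(-grid.bin_centers / 2.5)
        np.testing.assert_allclose(
            convolve_irf(decay, measured, grid),
            convolve_irf(decay, GaussianIrf(1.5, 0.15), grid), rtol=1e-12)

    def test_measured_irf_grid_mismatch_raises(self):
        grid = TimeGrid.from_window(12.5, 250)
        other = TimeGrid.from_window(12.5, 128)
        measured = MeasuredIrf(DecayHistogram(other, np.ones(128)))
        with pytest.raises(GridMismatchError):
            convolve_irf(np.ones(250), measured, grid)


class TestModelCurve:
    def test_zero_amplitude_gives_zero_curve(self):
        grid = TimeGrid.from_window(12.5, 250)
        model = CompositeDecayModel(
            (ExpComponent(0.0, 0.4), ExpComponent(0.0, 2.8)),
            irf=GaussianIrf(1.0, 0.1))
        assert np.all(model_curve(model, grid) == 0)

    def test_tail_mode_equals_pure_decay(self):
        grid = TimeGrid.from_window(12.5, 250)
        model = mono(100.0, 2.5)
        np.testing.assert_array_equal(
            model_curve(model, grid, t0=1.0), pure_decay(model, grid, t0=1.0))

    def test_bi_equals_sum_of_separately_convolved_monos(self):
        grid = TimeGrid.from_window(12.5, 250)
        irf = GaussianIrf(1.0, 0.1)
        bi = CompositeDecayModel(
            (ExpComponent(30.0, 0.4), ExpComponent(70.0, 2.8)), irf=irf)
        sep = (model_curve(mono(30.0, 0.4, irf), grid)
               + model_curve(mono(70.0, 2.8, irf), grid))
        np.testing.assert_allclose(model_curve(bi, grid), sep,
                                   rtol=0, atol=1e-12 * sep.max())

    def test_monotone_after_irf(self):
        grid = TimeGrid.from_window(12.5, 250)
        model = CompositeDecayModel(
            (ExpComponent(20.0, 0.4), ExpComponent(80.0, 2.8)),
            irf=GaussianIrf(1.0, 0.1))
        curve = model_curve(model, grid)
        after = curve[grid.bin_centers > 1.0 + 5 * 0.1]
        assert np.all(np.diff(after) <= 0)

    def test_shorter_lifetime_is_autofluorescence(self):
        model = CompositeDecayModel(
            (ExpComponent(1.0, 2.8), ExpComponent(2.0, 0.4)))
        assert model.autofluorescence.lifetime == 0.4
        assert model.signal.lifetime == 2.8
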