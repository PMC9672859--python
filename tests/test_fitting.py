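"""Poisson NLL and maximum-likelihood fitting tests."""
import numpy as np
import pytest

from flimkit.decay_model import (
    CompositeDecayModel,
    ExpComponent,
    GaussianIrf,
    model_curve,
)
from flimkit.errors import InvalidParameterError, LowCountsError
from flimkit.fitting import FitConfig, fit_decay, poisson_nll
from flimkit.histogram import DecayHistogram

from conftest import make_decay


class TestPoissonNll:
    def test_unit_case(self):
        assert poisson_nll([1.0], [1]) == pytest.approx(1.0)

    def test_hand_evaluated_formula(self):
        # (2 - 1 ln 2) + (1 - 2 ln 1) = 3 - ln 2
        assert poisson_nll([2.0, 1.0], [1, 2]) == pytest.approx(3 - np.log(2))

    def test_minimized_at_observed(self):
        """Perturbing any expected bin away from observed raises the NLL."""
        observed = np.array([5.0, 2.0, 9.0, 1.0])
        base = poisson_nll(observed, observed)
        for i in range(len(observed)):
            for eps in (-0.3, -0.05, 0.05, 0.3):
                perturbed = observed.astype(float).copy()
                perturbed[i] += eps
                assert poisson_nll(perturbed, observed) > base

    def test_negative_expected_raises(self):
        with pytest.raises(InvalidParameterError):
            poisson_nll([-1.0, 2.0], [0, 1])

    def test_zero_expected_is_floored_not_fatal(self):
        value = poisson_nll([0.0, 2.0], [0, 2])
        assert np.isfinite(value)


class TestFitDecay:
    def test_noiseless_recovery(self, grid):
        """Fitting the exact model curve recovers tau to relative 1e-3."""
        truth = CompositeDecayModel((ExpComponent(400.0, 2.2),),
                                    irf=GaussianIrf(1.0, 0.12))
        counts = np.round(model_curve(truth, grid)).astype(int)
        hist = DecayHistogram(grid, counts)
        result = fit_decay(hist, FitConfig(model_order="mono",
                                           endpoint_policy="full"))
        assert result.converged
        assert result.signal_lifetime == pytest.approx(2.2, rel=1e-3)

    def test_poisson_recovery_within_2pct(self):
        hist = make_decay(11, n_photons=100_000, tau_signal=2.5)
        result = fit_decay(hist, FitConfig(model_order="mono",
                                           endpoint_policy="full"))
        assert result.converged
        assert result.signal_lifetime == pytest.approx(2.5, rel=0.02)
        assert result.model.irf.sigma == pytest.approx(0.1, rel=0.15)

    def test_degenerate_bi_component_vanishes(self, grid):
        """Fitting bi to a decay with one true component: the absent
        component's amplitude fraction collapses to ~0."""
        truth = CompositeDecayModel((ExpComponent(600.0, 0.4),),
                                    irf=GaussianIrf(1.0, 0.1))
        counts = np.round(model_curve(truth, grid)).astype(int)
        result = fit_decay(DecayHistogram(grid, counts),
                           FitConfig(model_order="bi",
                                     endpoint_policy="full"))
        assert min(result.amplitude_fractions) < 1e-3

    def test_bit_identical_reruns(self):
        hist = make_decay(13, n_photons=20_000)
        config = FitConfig(model_order="auto", endpoint_policy="auto",
                           rng_seed=5)
        a = fit_decay(hist, config)
        b = fit_decay(hist, config)
        assert a.nll == b.nll
        assert a.signal_lifetime == b.signal_lifetime
        assert a.n_bins_used == b.n_bins_used
        assert a.amplitude_fractions == b.amplitude_fractions

    def test_frozen_parameters_pass_through_unchanged(self):
        hist = make_decay(14, n_photons=20_000, fraction_auto=0.25)
        fixed = {"tau_auto": 0.4, "mu": 1.0, "sigma": 0.1}
        result = fit_decay(hist, FitConfig(model_order="bi", fixed=fixed,
                                           endpoint_policy="full"))
        assert result.auto_lifetime == 0.4
        assert result.model.irf.mu == 1.0
        assert result.model.irf.sigma == 0.1

    def test_likelihood_dominance_over_truth(self, grid):
        """The fitted NLL is at least as good as the truth parameters'."""
        hist = make_decay(15, n_photons=30_000, fraction_auto=0.25,
                          tau_signal=2.8)
        result = fit_decay(hist, FitConfig(model_order="bi",
                                           endpoint_policy="full"))
        # evaluate the truth-shaped model with MLE amplitudes fixed at
        # the generative expectation
        n = hist.total
        auto = model_curve(CompositeDecayModel(
            (ExpComponent(1.0, 0.4),), irf=GaussianIrf(1.0, 0.1)), grid)
        sig = model_curve(CompositeDecayModel(
            (ExpComponent(1.0, 2.8),), irf=GaussianIrf(1.0, 0.1)), grid)
        truth_curve = (0.25 * n * auto / auto.sum()
                       + 0.75 * n * sig / sig.sum())
        assert result.nll <= poisson_nll(truth_curve, hist.counts)

    def test_low_counts_raises(self, grid):
        hist = DecayHistogram(grid, np.zeros(250, dtype=int))
        with pytest.raises(LowCountsError):
            fit_decay(hist, FitConfig())

    def test_tail_mode_recovery(self):
        hist = make_decay(16, n_photons=50_000, tau_signal=3.0)
        result = fit_decay(hist, FitConfig(mode="tail", model_order="mono",
                                           endpoint_policy="full"))
        assert result.converged
        assert result.signal_lifetime == pytest.approx(3.0, rel=0.05)

    def test_unknown_fixed_parameter_rejected(self):
        with pytest.raises(InvalidParameterError):
            FitConfig(fixed={"bogus": 1.0})


class TestEstimatorConsistency:
    def test_median_error_small_and_bias_shrinks(self):
        """tau-hat is consistent: error median < 3% at 1e4 photons and
        shrinks as the photon budget grows."""
        medians = {}
        for n_photons, n_rep in [(1_000, 12), (10_000, 12), (100_000, 6)]:
            errs = []
            for rep in range(n_rep):
                hist = make_decay(500 + rep, n_photons=n_photons)
                res = fit_decay(hist, FitConfig(model_order="mono",
                                                endpoint_policy="full"))
                errs.append(abs(res.signal_lifetime - 2.5) / 2.5)
            medians[n_photons] = float(np.median(errs))
        assert medians[10_000] < 0.03
        assert medians[1_000] > medians[10_000] > medians[100_000]
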