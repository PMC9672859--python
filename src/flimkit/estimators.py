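"""Scikit-learn style estimator interface to the decay fitter.

:class:`DecayFitter` wraps :func:`flimkit.fitting.fit_decay` in a
``fit``/``predict`` estimator so decay fits compose with scikit-learn
model selection and pipelines; all hyperparameters are constructor
arguments and all fitted quantities are trailing-underscore attributes.
"""
from __future__ import annotations

from typing import Optional

import numpy as np
from sklearn.base import BaseEstimator

from .errors import InvalidParameterError
from .fitting import FitConfig, FitResult, fit_decay
from .histogram import DecayHistogram, TimeGrid


class DecayFitter(BaseEstimator):
    """Poisson maximum-likelihood fitter for TCSPC decay histograms.

    Parameters mirror :class:`flimkit.fitting.FitConfig`; fixing
    ``tau_auto``, ``irf_mu`` and ``irf_sigma`` turns the fitter into the
    calibrated segment fitter (signal lifetime and amplitudes free).

    Examples
    --------
    >>> fitter = DecayFitter(model_order="mono", endpoint_policy="full")
    >>> fitter.fit(time_ns, counts)            # doctest: +SKIP
    >>> fitter.tau_signal_                     # doctest: +SKIP
    2.51
    """

    def __init__(self, mode: str = "convolution", model_order: str = "auto",
                 tau_auto: Optional[float] = None,
                 tau_signal: Optional[float] = None,
                 irf_mu: Optional[float] = None,
                 irf_sigma: Optional[float] = None,
                 endpoint_policy: object = "auto",
                 endpoint_criterion: str = "mean_deviance",
                 endpoint_stride: int = 16,
                 endpoint_min_window: int = 24,
                 multistart_count: int = 3,
                 min_counts: int = 100,
                 tail_start: Optional[int] = None,
                 min_fraction: float = 0.01,
                 min_separation: float = 1.5,
                 random_state: int = 0):
        self.mode = mode
        self.model_order = model_order
        self.tau_auto = tau_auto
        self.tau_signal = tau_signal
        self.irf_mu = irf_mu
        self.irf_sigma = irf_sigma
        self.endpoint_policy = endpoint_policy
        self.endpoint_criterion = endpoint_criterion
        self.endpoint_stride = endpoint_stride
        self.endpoint_min_window = endpoint_min_window
        self.multistart_count = multistart_count
        self.min_counts = min_counts
        self.tail_start = tail_start
        self.min_fraction = min_fraction
        self.min_separation = min_separation
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _config(self) -> FitConfig:
        fixed = {}
        if self.tau_auto is not None:
            fixed["tau_auto"] = float(self.tau_auto)
        if self.tau_signal is not None:
            fixed["tau_signal"] = float(self.tau_signal)
        if self.irf_mu is not None:
            fixed["mu"] = float(self.irf_mu)
        if self.irf_sigma is not None:
            fixed["sigma"] = float(self.irf_sigma)
        return FitConfig(
            mode=self.mode, model_order=self.model_order, fixed=fixed,
            endpoint_policy=self.endpoint_policy,
            endpoint_criterion=self.endpoint_criterion,
            endpoint_stride=self.endpoint_stride,
            endpoint_min_window=self.endpoint_min_window,
            multistart_count=self.multistart_count,
            min_counts=self.min_counts, rng_seed=self.random_state,
            tail_start=self.tail_start, min_fraction=self.min_fraction,
            min_separation=self.min_separation,
        )

    @staticmethod
    def _as_histogram(X, y=None) -> DecayHistogram:
        if isinstance(X, DecayHistogram):
            return X
        X = np.asarray(X)
        if y is not None:
            return DecayHistogram(TimeGrid(np.asarray(X, float)),
                                  np.asarray(y))
        if X.ndim == 2 and X.shape[1] == 2:
            return DecayHistogram(TimeGrid(X[:, 0].astype(float)), X[:, 1])
        raise InvalidParameterError(
            "pass a DecayHistogram, an (n, 2) [time, counts] array, or "
            "fit(time, counts)"
        )

    def fit(self, X, y=None) -> "DecayFitter":
        """Fit the decay model.

        ``X`` may be a :class:`DecayHistogram`, an ``(n, 2)`` array of
        ``[time_ns, counts]`` columns, or the time vector with counts
        passed as ``y``.
        """
        hist = self._as_histogram(X, y)
        result = fit_decay(hist, self._config())
        self._set_result(hist, result)
        return self

    def _set_result(self, hist: DecayHistogram, result: FitResult):
        self.grid_ = hist.grid
        self.result_ = result
        self.model_ = result.model
        self.nll_ = result.nll
        self.tau_signal_ = result.signal_lifetime
        self.tau_auto_ = result.auto_lifetime
        self.irf_mu_ = result.model.irf.mu if result.model.irf else None
        self.irf_sigma_ = result.model.irf.sigma if result.model.irf else None
        self.amplitude_fractions_ = result.amplitude_fractions
        self.n_bins_used_ = result.n_bins_used
        self.model_order_ = result.model_order_used
        self.converged_ = result.converged
        self.endpoint_trace_ = result.endpoint_trace

    def predict(self, X=None) -> np.ndarray:
        """Expected counts per bin of the fitted model.

        With ``X=None`` the training grid is used; otherwise ``X`` is a
        vector of bin-center times on a uniform grid.
        """
        from .decay_model import model_curve

        if not hasattr(self, "result_"):
            raise InvalidParameterError("fit before predict")
        grid = self.grid_ if X is None else TimeGrid(np.asarray(X, float))
        t0 = None
        if self.mode == "tail" and self.result_.tail_start is not None:
            t0 = float(self.grid_.bin_centers[self.result_.tail_start])
        return model_curve(self.model_, grid, t0=t0)

    def score(self, X=None, y=None) -> float:
        """Negative NLL of the fit (higher is better, sklearn convention)."""
        if not hasattr(self, "result_"):
            raise InvalidParameterError("fit before score")
        return -self.nll_
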