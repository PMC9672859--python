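"""Poisson maximum-likelihood fitting of TCSPC decay histograms.

The fit objective is the Poisson negative log-likelihood (NLL)

    NLL = sum_i (m_i - n_i ln m_i)

over the included bins, with the n_i!-dependent constant dropped; it is
the statistically correct objective for photon-counting data and
matters most at the low counts typical of in-vivo segments.

The model curve is linear in the component amplitudes, so the
amplitudes are profiled out at every objective evaluation with a
monotone multiplicative (EM) update; the outer simplex search then only
runs over the nonlinear parameters (lifetimes and the Gaussian IRF
``mu``/``sigma``).  This makes the calibrated segment fit — signal
lifetime free, everything else frozen — a one-dimensional search, which
is what keeps whole-image pipelines fast.

Endpoint selection
------------------
Background or scattered light accumulates in the late bins of the decay
window and biases lifetimes upward if included.  The endpoint (last bin
included in the fit) is therefore treated as a fit variable: the fit is
repeated over a sweep of candidate endpoints and a per-point
goodness-of-fit criterion is optimized.  The default criterion is the
Poisson deviance per residual degree of freedom: ranges the model
describes score ~1 or below, so the longest statistically acceptable
range is kept (nothing is cut on clean data); once background bins the
model cannot describe enter, the criterion rises well above 1 and the
sweep cuts at its minimum.  A second criterion, ``nll_sqrt``
(maximize NLL / sqrt(N)), is available via
``FitConfig.endpoint_criterion``.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.optimize import minimize

from .decay_model import (
    CompositeDecayModel,
    ExpComponent,
    GaussianIrf,
    gaussian_kernel,
    sampled_exp,
)
from .errors import (
    DegenerateRangeError,
    FitFailureError,
    InvalidParameterError,
    LowCountsError,
)
from .histogram import DecayHistogram

#: floor applied to expected counts before taking logarithms
NLL_FLOOR = 1e-12

#: parameter names that may be frozen via FitConfig.fixed
FIXABLE = ("tau_auto", "tau_signal", "mu", "sigma")

_BIG = 1e30


@dataclass(frozen=True)
class FitConfig:
    """Configuration of a decay fit.

    Parameters
    ----------
    mode : "convolution" or "tail"
        Convolution mode fits the full curve including the IRF rise;
        tail mode fits a pure exponential from ``tail_start`` onward.
    model_order : "mono", "bi" or "auto"
        "auto" fits both and keeps the bi-exponential only if it is
        justified (see :func:`assess_model_order`).
    fixed : dict
        Frozen parameters by name ("tau_auto", "tau_signal", "mu",
        "sigma"); frozen values pass through to the result untouched.
    endpoint_policy : "auto", "full" or int
        "auto" sweeps candidate endpoints; "full" uses every bin; an
        integer fixes the endpoint (number of bins used).
    endpoint_criterion : "mean_deviance" or "nll_sqrt"
        Goodness-of-fit criterion optimized by the endpoint sweep.
    """

    mode: str = "convolution"
    model_order: str = "auto"
    fixed: dict = field(default_factory=dict)
    endpoint_policy: object = "auto"
    endpoint_criterion: str = "mean_deviance"
    endpoint_stride: int = 16
    endpoint_min_window: int = 24
    multistart_count: int = 3
    min_counts: int = 100
    rng_seed: int = 0
    tail_start: Optional[int] = None
    min_fraction: float = 0.01
    min_separation: float = 1.5

    def __post_init__(self):
        if self.mode not in ("convolution", "tail"):
            raise InvalidParameterError(f"unknown mode {self.mode!r}")
        if self.model_order not in ("mono", "bi", "auto"):
            raise InvalidParameterError(f"unknown model_order {self.model_order!r}")
        if self.endpoint_criterion not in ("mean_deviance", "nll_sqrt"):
            raise InvalidParameterError(
                f"unknown endpoint_criterion {self.endpoint_criterion!r}"
            )
        if self.multistart_count < 1:
            raise InvalidParameterError("multistart_count must be >= 1")
        for name in self.fixed:
            if name not in FIXABLE:
                raise InvalidParameterError(
                    f"cannot fix unknown parameter {name!r}; choose from {FIXABLE}"
                )


@dataclass(frozen=True)
class FitResult:
    """Outcome of a decay fit."""

    model: CompositeDecayModel
    nll: float
    n_bins_used: int
    model_order_used: str
    converged: bool
    signal_lifetime: float
    auto_lifetime: Optional[float]
    amplitude_fractions: tuple
    n_free_parameters: int
    tail_start: Optional[int] = None
    endpoint_trace: Optional[np.ndarray] = None  # columns: N, nll, criterion
    message: str = ""


def poisson_nll(expected: np.ndarray, observed: np.ndarray,
                floor: float = NLL_FLOOR) -> float:
    """Poisson negative log-likelihood ``sum(m - n ln m)`` (constant dropped).

    Expected values are clamped at ``floor`` before the logarithm;
    negative or non-finite expected values raise.
    """
    m = np.asarray(expected, dtype=float)
    n = np.asarray(observed, dtype=float)
    if m.shape != n.shape:
        raise InvalidParameterError("expected/observed length mismatch")
    if np.any(n < 0):
        raise InvalidParameterError("observed counts must be non-negative")
    if not np.all(np.isfinite(m)) or np.any(m < 0):
        raise InvalidParameterError("expected values must be finite and >= 0")
    m = np.maximum(m, floor)
    return float(np.sum(m - n * np.log(m)))


def poisson_deviance(expected: np.ndarray, observed: np.ndarray,
                     floor: float = NLL_FLOOR) -> float:
    """Poisson deviance ``2 sum[m - n + n ln(n/m)]`` (zero for a saturated fit)."""
    m = np.maximum(np.asarray(expected, dtype=float), floor)
    n = np.asarray(observed, dtype=float)
    terms = m - n
    pos = n > 0
    terms[pos] += n[pos] * np.log(n[pos] / m[pos])
    return float(2.0 * terms.sum())


# ---------------------------------------------------------------------------
# internal fitting machinery


def _profile_amplitudes(U: np.ndarray, counts: np.ndarray,
                        max_iter: int = 500, rtol: float = 1e-12,
                        A0: Optional[np.ndarray] = None):
    """MLE amplitudes for ``m = sum_c A_c U_c`` under Poisson counts.

    Multiplicative EM updates: monotone in the likelihood, preserves
    positivity, exact in one step for a single component.  ``A0`` warm
    starts the iteration (successive optimizer steps move amplitudes
    only slightly).
    """
    usums = U.sum(axis=1)
    ok = usums > 0
    A = np.zeros(U.shape[0])
    total = counts.sum()
    if total <= 0 or not ok.any():
        return A, poisson_nll(np.zeros_like(counts), counts)
    if A0 is not None and A0.shape == A.shape and np.all(A0[ok] > 0):
        A[ok] = A0[ok]
    else:
        A[ok] = total / (ok.sum() * usums[ok])
    Uok, usok = U[ok], usums[ok]
    Aok = A[ok]
    for _ in range(max_iter):
        m = np.maximum(Aok @ Uok, NLL_FLOOR)
        new = Aok * (Uok @ (counts / m)) / usok
        if np.all(np.abs(new - Aok) <= rtol * np.maximum(Aok, 1e-300)):
            Aok = new
            break
        Aok = new
    A[ok] = Aok
    nll = poisson_nll(A @ U, counts)
    return A, nll


class _FitProblem:
    """One histogram + configuration, truncated at a fixed endpoint."""

    def __init__(self, hist: DecayHistogram, config: FitConfig,
                 n_used: int, order: str):
        self.hist = hist
        self.config = config
        self.n_used = int(n_used)
        self.order = order
        self.grid = hist.grid
        n = self.grid.n_bins
        self.nfft = 1 << int(np.ceil(np.log2(2 * n)))
        self._kernel_cache = (None, None)
        self._warm_A = None
        if config.mode == "tail":
            ts = config.tail_start
            if ts is None:
                ts = _default_tail_start(hist)
            self.tail_start = int(ts)
        else:
            self.tail_start = 0
        if self.n_used - self.tail_start < 4:
            raise DegenerateRangeError(
                f"fit window [{self.tail_start}, {self.n_used}) too short"
            )
        self.window = slice(self.tail_start, self.n_used)
        self.counts_w = hist.counts[self.window].astype(float)
        self.n_points = self.n_used - self.tail_start
        # nonlinear parameters, minus frozen ones
        if order == "bi":
            names = ["tau_auto", "tau_signal"]
        else:
            names = ["tau_signal"]
        if config.mode == "convolution":
            names += ["mu", "sigma"]
        self.free_names = [p for p in names if p not in config.fixed]
        self.all_names = names
        self.n_free = len(self.free_names) + (2 if order == "bi" else 1)

    # -- parameter vector <-> dict ------------------------------------
    def encode(self, params: dict) -> np.ndarray:
        x = []
        for name in self.free_names:
            v = params[name]
            x.append(v if name == "mu" else np.log(v))
        return np.array(x)

    def decode(self, x: np.ndarray) -> dict:
        params = dict(self.config.fixed)
        for name, v in zip(self.free_names, x):
            params[name] = v if name == "mu" else float(np.exp(v))
        return params

    # -- model evaluation ---------------------------------------------
    def basis(self, params: dict) -> Optional[np.ndarray]:
        """Unit-amplitude component curves over the fit window.

        Returns None for out-of-domain parameters (signals a penalty).
        """
        taus = ([params["tau_auto"], params["tau_signal"]]
                if self.order == "bi" else [params["tau_signal"]])
        # lifetimes below half a bin are unresolvable on this grid
        if any(not np.isfinite(t) or t < 0.5 * self.grid.dt for t in taus):
            return None
        if self.order == "bi" and taus[1] < taus[0]:
            return None  # signal lifetime must stay the longer one
        if self.config.mode == "tail":
            t = self.grid.bin_centers[self.window]
            t0 = self.grid.bin_centers[self.tail_start]
            U = np.exp(-(t - t0)[None, :] / np.array(taus)[:, None])
            return U
        mu, sigma = params["mu"], params["sigma"]
        lo, hi = self.grid.span
        if not (np.isfinite(mu) and lo <= mu <= hi):
            return None
        # sigma below a tenth of a bin is unresolvable and can underflow
        if not (np.isfinite(sigma) and 0.1 * self.grid.dt <= sigma <= (hi - lo)):
            return None
        d = np.stack([sampled_exp(tau, self.grid.n_bins, self.grid.dt)
                      for tau in taus])
        # kernel FFT cache pays off when mu/sigma are frozen (segment fits)
        key = (mu, sigma)
        if self._kernel_cache[0] == key:
            K = self._kernel_cache[1]
        else:
            kernel = gaussian_kernel(GaussianIrf(mu=mu, sigma=sigma), self.grid)
            K = np.fft.rfft(kernel, self.nfft)
            self._kernel_cache = (key, K)
        U = np.fft.irfft(np.fft.rfft(d, self.nfft, axis=1) * K,
                         self.nfft, axis=1)[:, :self.grid.n_bins]
        return np.clip(U[:, self.window], 0.0, None)

    def objective(self, x: np.ndarray) -> float:
        U = self.basis(self.decode(x))
        if U is None:
            return _BIG
        A, nll = _profile_amplitudes(U, self.counts_w, max_iter=120,
                                     rtol=1e-9, A0=self._warm_A)
        self._warm_A = A
        return nll if np.isfinite(nll) else _BIG

    def solve(self, params: dict):
        """Amplitudes + NLL at given nonlinear parameters (cold, tight EM)."""
        U = self.basis(params)
        if U is None:
            raise InvalidParameterError(f"parameters out of domain: {params}")
        return _profile_amplitudes(U, self.counts_w)


def _default_tail_start(hist: DecayHistogram) -> int:
    """Peak bin plus ~5 sigma of the rising edge (beyond IRF influence)."""
    peak = hist.peak_index
    sigma0 = _init_sigma(hist, peak)
    return min(peak + int(np.ceil(5 * sigma0 / hist.grid.dt)),
               hist.grid.n_bins - 8)


def _init_sigma(hist: DecayHistogram, peak: int) -> float:
    """Rising-edge half-width at half-maximum / 1.177."""
    counts = hist.counts
    half = counts[peak] / 2.0
    idx = np.nonzero(counts[: peak + 1] >= half)[0]
    first = idx[0] if idx.size else peak
    hwhm = (peak - first) * hist.grid.dt
    return max(hwhm / 1.177, hist.grid.dt)


def _initial_params(hist: DecayHistogram, config: FitConfig, n_used: int,
                    order: str) -> dict:
    """Cheap scale-aware starting values derived from the data."""
    counts = hist.counts[:n_used].astype(float)
    t = hist.grid.bin_centers[:n_used]
    peak = int(np.argmax(counts))
    mu0 = float(t[peak])
    sigma0 = _init_sigma(hist, peak)
    after = counts[peak:]
    if after.sum() > 0:
        tau0 = float(np.sum(after * (t[peak:] - t[peak])) / after.sum())
    else:
        tau0 = hist.grid.dt
    tau0 = max(tau0, 2 * hist.grid.dt)
    params = {"tau_signal": tau0, "mu": mu0, "sigma": sigma0}
    if order == "bi":
        params["tau_auto"] = max(tau0 / 5.0, sigma0)
        # keep ordering sane if tau_signal ended up tiny
        params["tau_signal"] = max(tau0, 1.5 * params["tau_auto"])
    for name, value in config.fixed.items():
        params[name] = value
    if "tau_auto" in config.fixed and order == "bi":
        params["tau_signal"] = max(params["tau_signal"],
                                   1.05 * config.fixed["tau_auto"])
    return params


#: lifetime perturbation factors used by the multistart loop
MULTISTART_SCALES = (1.0, 0.5, 2.0, 0.25, 4.0)


def _fit_at_endpoint(hist: DecayHistogram, config: FitConfig, n_used: int,
                     order: str, init: Optional[dict] = None,
                     multistart: bool = True) -> FitResult:
    problem = _FitProblem(hist, config, n_used, order)
    base = _initial_params(hist, config, n_used, order)
    if init:
        base.update({k: v for k, v in init.items() if k in problem.all_names})
        base.update(config.fixed)
    scales = MULTISTART_SCALES[: config.multistart_count] if multistart else (1.0,)
    best = None
    for scale in scales:
        start = dict(base)
        for name in ("tau_auto", "tau_signal"):
            if name in problem.free_names:
                start[name] = base[name] * scale
        if "tau_auto" in start and "tau_signal" in start:
            start["tau_signal"] = max(start["tau_signal"], 1.05 * start["tau_auto"])
        x0 = problem.encode(start)
        if problem.objective(x0) >= _BIG:
            continue
        opts = {"xatol": 1e-4, "fatol": 1e-3,
                "maxiter": 600 * max(1, x0.size),
                "maxfev": 600 * max(1, x0.size)}
        res = minimize(problem.objective, x0, method="Nelder-Mead",
                       options=opts)
        # restart once from the solution: NM simplices can stall early
        res2 = minimize(problem.objective, res.x, method="Nelder-Mead",
                        options=opts)
        if res2.fun < res.fun:
            res = res2
        cand = (res.fun, problem.decode(res.x), bool(res.success))
        if best is None or cand[0] < best[0] - 1e-9 or (
            abs(cand[0] - best[0]) <= 1e-9
            and cand[1]["tau_signal"] < best[1]["tau_signal"]
        ):
            best = cand
    if best is None:
        raise FitFailureError("no feasible starting point for fit")
    nll, params, success = best
    amplitudes, nll = problem.solve(params)
    return _package_result(problem, params, amplitudes, nll, success)


def _package_result(problem: _FitProblem, params: dict, amplitudes: np.ndarray,
                    nll: float, converged: bool) -> FitResult:
    config = problem.config
    if problem.order == "bi":
        taus = (params["tau_auto"], params["tau_signal"])
    else:
        taus = (params["tau_signal"],)
    comps = tuple(ExpComponent(amplitude=float(a), lifetime=float(tau))
                  for a, tau in zip(amplitudes, taus))
    irf = (GaussianIrf(mu=float(params["mu"]), sigma=float(params["sigma"]))
           if config.mode == "convolution" else None)
    model = CompositeDecayModel(components=comps, irf=irf)
    U = problem.basis(params)
    contrib = amplitudes * U.sum(axis=1)
    total = contrib.sum()
    fractions = tuple(float(c / total) if total > 0 else 0.0 for c in contrib)
    return FitResult(
        model=model,
        nll=float(nll),
        n_bins_used=problem.n_used,
        model_order_used=problem.order,
        converged=bool(converged and np.isfinite(nll)),
        signal_lifetime=float(model.signal.lifetime),
        auto_lifetime=(float(model.autofluorescence.lifetime)
                       if model.autofluorescence is not None else None),
        amplitude_fractions=fractions,
        n_free_parameters=problem.n_free,
        tail_start=problem.tail_start if config.mode == "tail" else None,
    )


def _criterion(result: FitResult, problem: _FitProblem, expected: np.ndarray,
               how: str) -> float:
    """Endpoint criterion as a value to *minimize*.

    ``mean_deviance`` is the Poisson deviance per residual degree of
    freedom (N - k); without the dof correction the criterion would be
    biased low at short ranges, where the k parameters absorb a larger
    share of the points.
    """
    n_points = problem.n_points
    if how == "nll_sqrt":
        return -result.nll / np.sqrt(n_points)  # literal: maximize NLL/sqrt(N)
    dev = poisson_deviance(expected, problem.counts_w)
    dof = max(n_points - result.n_free_parameters, 1)
    return dev / dof


def _result_expected(problem: _FitProblem, result: FitResult) -> np.ndarray:
    params = {"tau_signal": result.signal_lifetime}
    if result.auto_lifetime is not None:
        params["tau_auto"] = result.auto_lifetime
    if result.model.irf is not None:
        params["mu"] = result.model.irf.mu
        params["sigma"] = result.model.irf.sigma
    U = problem.basis(params)
    A = np.array([c.amplitude for c in result.model.components])
    return A @ U


# ---------------------------------------------------------------------------
# public operations


def fit_decay(hist: DecayHistogram, config: Optional[FitConfig] = None,
              init: Optional[CompositeDecayModel] = None) -> FitResult:
    """Fit a decay histogram per ``config``; see :class:`FitConfig`.

    Returns an unconverged :class:`FitResult` (never a silent success)
    when the optimizer exhausts its multistart budget without
    converging; raises :class:`LowCountsError` below ``min_counts``.
    """
    config = config or FitConfig()
    if hist.total < config.min_counts:
        raise LowCountsError(
            f"histogram has {hist.total} photons, need >= {config.min_counts}"
        )
    init_params = _model_to_params(init) if init is not None else None
    if config.endpoint_policy == "auto":
        _, result = choose_endpoint(hist, config, init=init_params)
        return result
    n_used = (hist.grid.n_bins if config.endpoint_policy in ("full", None)
              else int(config.endpoint_policy))
    return _fit_with_order(hist, config, n_used, init_params)


def _model_to_params(model: CompositeDecayModel) -> dict:
    params = {"tau_signal": model.signal.lifetime}
    if model.autofluorescence is not None:
        params["tau_auto"] = model.autofluorescence.lifetime
    if isinstance(model.irf, GaussianIrf):
        params["mu"] = model.irf.mu
        params["sigma"] = model.irf.sigma
    return params


def _fit_with_order(hist, config, n_used, init=None,
                    trace: Optional[np.ndarray] = None) -> FitResult:
    if config.model_order == "mono":
        result = _fit_at_endpoint(hist, config, n_used, "mono", init)
        return replace(result, endpoint_trace=trace)
    bi = _fit_at_endpoint(hist, config, n_used, "bi", init)
    if config.model_order == "bi":
        return replace(bi, endpoint_trace=trace)
    mono = _fit_at_endpoint(hist, config, n_used, "mono", init)
    choice = assess_model_order(bi, mono, min_fraction=config.min_fraction,
                                min_separation=config.min_separation)
    return replace(bi if choice == "bi" else mono, endpoint_trace=trace)


def choose_endpoint(hist: DecayHistogram, config: Optional[FitConfig] = None,
                    init: Optional[dict] = None):
    """Sweep candidate endpoints and return ``(endpoint, FitResult)``.

    Candidates run from (peak bin + ``endpoint_min_window``) to the full
    range on ``endpoint_stride``, with local refinement around the
    best coarse candidate.  Each candidate is refit (warm-started from
    its neighbour) and scored by ``endpoint_criterion``; the sweep trace
    ``(N, nll, criterion)`` is attached to the returned result for
    plotting.
    """
    config = config or FitConfig()
    n_bins = hist.grid.n_bins
    start = hist.peak_index + config.endpoint_min_window
    candidates = list(range(start, n_bins, config.endpoint_stride))
    if candidates and candidates[-1] != n_bins:
        candidates.append(n_bins)
    if len(candidates) < 2:
        raise DegenerateRangeError(
            f"only {len(candidates)} candidate endpoints between bin "
            f"{start} and {n_bins}"
        )
    order = "bi" if config.model_order in ("bi", "auto") else "mono"

    rows = {}
    warm = init

    def _score(n_used, warm_params, multistart):
        problem = _FitProblem(hist, config, n_used, order)
        result = _fit_at_endpoint(hist, config, n_used, order,
                                  init=warm_params, multistart=multistart)
        expected = _result_expected(problem, result)
        crit = _criterion(result, problem, expected, config.endpoint_criterion)
        rows[n_used] = (result.nll, crit)
        return result, crit

    warms = {}
    for i, n_used in enumerate(candidates):
        result, crit = _score(n_used, warm, multistart=(i == 0))
        warm = _model_to_params(result.model)
        warms[n_used] = warm

    def _select(evaluated):
        """Pick the endpoint given criterion values per candidate.

        For ``mean_deviance``: a range whose reduced deviance is
        statistically acceptable (within one SE of 1, the asymptotic
        reduced-chi-square expectation with SE sqrt(2/dof)) should not
        be cut, so the longest acceptable range wins; when no range is
        acceptable — background the model cannot describe — the range
        with the smallest reduced deviance wins.  For ``nll_sqrt``:
        the literal arg-optimum.
        """
        ns = sorted(evaluated)
        crits = {n: rows[n][1] for n in ns}
        if config.endpoint_criterion == "nll_sqrt":
            return min(ns, key=lambda n: (crits[n], n))
        n_min = min(ns, key=lambda n: (crits[n], n))
        prob = _FitProblem(hist, config, n_min, order)
        se = np.sqrt(2.0 / max(prob.n_points - prob.n_free, 1))
        if crits[n_min] > 1.0 + se:
            return n_min
        threshold = max(1.0, crits[n_min]) + se
        return max(n for n in ns if crits[n] <= threshold)

    best_n = _select(candidates)
    # local refinement around the coarse selection
    refine_step = max(1, config.endpoint_stride // 4)
    lo = max(start, best_n - config.endpoint_stride + refine_step)
    hi = min(n_bins, best_n + config.endpoint_stride)
    for n_used in range(lo, hi + 1, refine_step):
        if n_used in rows:
            continue
        result, _ = _score(n_used, warms[best_n], multistart=False)
        warms[n_used] = _model_to_params(result.model)
    best_n = _select(rows)
    best_warm = warms[best_n]

    trace = np.array([[n, rows[n][0], rows[n][1]] for n in sorted(rows)])
    final = _fit_with_order(hist, config, best_n, best_warm, trace=trace)
    return best_n, final


def assess_model_order(bi: FitResult, mono: FitResult,
                       min_fraction: float = 0.01,
                       min_separation: float = 1.5) -> str:
    """Decide whether the bi-exponential model is justified.

    Keeps "bi" only if every amplitude fraction is at least
    ``min_fraction``, the lifetimes are separated by at least
    ``min_separation``, and BIC (on the Poisson likelihood, penalizing
    the two extra parameters) favors it; otherwise "mono".
    """
    if not bi.converged and not mono.converged:
        raise FitFailureError("neither mono nor bi fit converged")
    if not bi.converged:
        return "mono"
    if not mono.converged:
        return "bi"
    if min(bi.amplitude_fractions) < min_fraction:
        return "mono"
    if bi.auto_lifetime is None:
        return "mono"
    if bi.signal_lifetime / bi.auto_lifetime < min_separation:
        return "mono"
    n_points = bi.n_bins_used - (bi.tail_start or 0)
    bic_bi = 2 * bi.nll + bi.n_free_parameters * np.log(n_points)
    bic_mono = 2 * mono.nll + mono.n_free_parameters * np.log(n_points)
    return "bi" if bic_bi < bic_mono else "mono"
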