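"""Forward model of a measured FLIM decay.

The photon-arrival histogram recorded by a TCSPC system is modelled as a
sum of one or two exponential decays convolved with the instrument
response function (IRF).  The IRF is either a narrow Gaussian with
centre ``mu`` and width ``sigma`` (both in ns) or a measured histogram
on the same grid.  In convolution mode the exponential decay itself
always starts at the origin of the grid; the IRF carries the time shift,
which removes the degenerate (t0, mu) parameter pair.

Closed forms
------------
The convolution of ``A exp(-t/tau)`` (for t >= 0) with a unit-area
Gaussian is the exponentially modified Gaussian

    (A/2) exp(sigma^2/(2 tau^2) - (t - mu)/tau)
        * erfc((mu + sigma^2/tau - t) / (sigma sqrt(2)))

which :func:`exp_mod_gauss` implements.  It is used as an independent
oracle for the FFT path in the test-suite and acceptance checks.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .errors import GridMismatchError, InvalidParameterError
from .histogram import DecayHistogram, TimeGrid


@dataclass(frozen=True)
class ExpComponent:
    """One exponential decay component.

    ``amplitude`` is the expected count in the first bin of the
    un-convolved decay (dimensionless, >= 0); ``lifetime`` is in ns.
    """

    amplitude: float
    lifetime: float

    def __post_init__(self):
        if not np.isfinite(self.amplitude) or self.amplitude < 0:
            raise InvalidParameterError(f"amplitude must be >= 0, got {self.amplitude}")
        if not np.isfinite(self.lifetime) or self.lifetime <= 0:
            raise InvalidParameterError(f"lifetime must be > 0, got {self.lifetime}")


@dataclass(frozen=True)
class GaussianIrf:
    """Gaussian instrument response, centred at ``mu`` with width ``sigma`` (ns)."""

    mu: float
    sigma: float

    def __post_init__(self):
        if not np.isfinite(self.sigma) or self.sigma <= 0:
            raise InvalidParameterError(f"sigma must be > 0, got {self.sigma}")
        if not np.isfinite(self.mu):
            raise InvalidParameterError("mu must be finite")


@dataclass(frozen=True)
class MeasuredIrf:
    """A measured instrument response histogram, normalized to unit sum."""

    histogram: DecayHistogram

    def kernel(self, grid: TimeGrid) -> np.ndarray:
        if not self.histogram.grid.is_same(grid):
            raise GridMismatchError("measured IRF grid differs from data grid")
        counts = np.asarray(self.histogram.counts, dtype=float)
        total = counts.sum()
        if total <= 0:
            raise InvalidParameterError("measured IRF has zero total counts")
        return counts / total


Irf = Union[GaussianIrf, MeasuredIrf]


@dataclass(frozen=True)
class CompositeDecayModel:
    """One or two exponential components plus an optional IRF.

    With two components the shorter-lifetime one is the
    autofluorescence component; ``irf=None`` means tail mode (no
    convolution, decay starts at an explicit ``t0``).
    """

    components: tuple
    irf: Optional[Irf] = None

    def __post_init__(self):
        comps = tuple(self.components)
        if not 1 <= len(comps) <= 2:
            raise InvalidParameterError(
                f"model needs 1 or 2 components, got {len(comps)}"
            )
        # canonical order: shortest lifetime (autofluorescence) first
        comps = tuple(sorted(comps, key=lambda c: c.lifetime))
        object.__setattr__(self, "components", comps)

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def signal(self) -> ExpComponent:
        """The long-lifetime (sensor signal) component."""
        return self.components[-1]

    @property
    def autofluorescence(self) -> Optional[ExpComponent]:
        """The short-lifetime component, or None for a mono model."""
        return self.components[0] if len(self.components) == 2 else None


def pure_decay(model: CompositeDecayModel, grid: TimeGrid, t0: float = 0.0) -> np.ndarray:
    """Un-convolved multi-exponential decay sampled at bin centers.

    Value at bin i is ``sum_c A_c exp(-(t_i - t0)/tau_c)`` for
    ``t_i >= t0`` and zero before.
    """
    lo, hi = grid.span
    if not lo <= t0 <= hi:
        raise InvalidParameterError(f"t0={t0} outside grid span {grid.span}")
    t = grid.bin_centers - t0
    out = np.zeros(grid.n_bins)
    alive = t >= 0
    for comp in model.components:
        out[alive] += comp.amplitude * np.exp(-t[alive] / comp.lifetime)
    return out


def gaussian_kernel(irf: GaussianIrf, grid: TimeGrid) -> np.ndarray:
    """Gaussian IRF discretized at bin centers and renormalized to unit sum.

    Renormalization keeps total counts independent of the sigma/dt ratio
    and of edge truncation.
    """
    z = (grid.bin_centers - irf.mu) / irf.sigma
    k = np.exp(-0.5 * z * z)
    total = k.sum()
    if total <= 0:
        raise InvalidParameterError(
            f"Gaussian IRF (mu={irf.mu}, sigma={irf.sigma}) has no mass on the grid"
        )
    return k / total


def convolve_irf(decay: np.ndarray, irf: Irf, grid: TimeGrid) -> np.ndarray:
    """Discrete linear convolution of a decay curve with the IRF.

    Zero-padded FFT convolution (next power of two >= 2 n_bins) so the
    rising edge is never corrupted by circular wrap-around; the result
    is truncated to the grid length and clipped at zero to suppress
    FFT round-off ringing.
    """
    decay = np.asarray(decay, dtype=float)
    if decay.shape != (grid.n_bins,):
        raise GridMismatchError("decay length does not match grid")
    if isinstance(irf, MeasuredIrf):
        kernel = irf.kernel(grid)
    else:
        kernel = gaussian_kernel(irf, grid)
    n = grid.n_bins
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    out = np.fft.irfft(np.fft.rfft(decay, nfft) * np.fft.rfft(kernel, nfft), nfft)[:n]
    return np.clip(out, 0.0, None)


def model_curve(model: CompositeDecayModel, grid: TimeGrid,
                t0: Optional[float] = None) -> np.ndarray:
    """Expected counts per bin for a complete model.

    Convolution mode (``model.irf`` set): the pure decay starts at the
    grid origin and is convolved with the IRF.  Tail mode (no IRF):
    ``pure_decay`` from ``t0`` (default: first bin center).
    """
    if model.irf is None:
        if t0 is None:
            t0 = float(grid.bin_centers[0])
        return pure_decay(model, grid, t0=t0)
    decay = np.zeros(grid.n_bins)
    for comp in model.components:
        decay += comp.amplitude * sampled_exp(comp.lifetime, grid.n_bins, grid.dt)
    return convolve_irf(decay, model.irf, grid)


def sampled_exp(tau: float, n: int, dt: float) -> np.ndarray:
    """``exp(-s/tau)`` step-decay averaged over cells centred at ``k dt``.

    Cell k covers ``[max(0, (k-1/2) dt), (k+1/2) dt]``; exact averaging
    over the cell (rather than point sampling) removes the half-bin
    shift and O(dt) weight error that the jump at s=0 would otherwise
    introduce into the discrete convolution.
    """
    k = np.arange(n)
    upper = (k + 0.5) * dt
    lower = np.maximum((k - 0.5) * dt, 0.0)
    return (np.exp(-lower / tau) - np.exp(-upper / tau)) * (tau / dt)


def exp_mod_gauss(t: np.ndarray, amplitude: float, tau: float,
                  mu: float, sigma: float) -> np.ndarray:
    """Closed-form convolution of ``A exp(-t/tau)`` with a unit-area Gaussian.

    Exponentially modified Gaussian, evaluated in a numerically stable
    form via ``erfcx`` to avoid overflow of the exponential prefactor.
    """
    from scipy.special import erfc, erfcx

    t = np.asarray(t, dtype=float)
    arg = (mu + sigma * sigma / tau - t) / (sigma * np.sqrt(2.0))
    out = np.empty_like(arg)
    # rising edge (arg >= 0): erfc underflows, use scaled form; the
    # exponent collapses to -(t-mu)^2/(2 sigma^2)
    pos = arg >= 0
    z = (t - mu) / sigma
    out[pos] = 0.5 * amplitude * erfcx(arg[pos]) * np.exp(-0.5 * z[pos] ** 2)
    # decay tail (arg < 0): erfc -> 2, prefactor exponent is negative
    neg = ~pos
    expo = sigma * sigma / (2 * tau * tau) - (t[neg] - mu) / tau
    out[neg] = 0.5 * amplitude * np.exp(expo) * erfc(arg[neg])
    return out
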