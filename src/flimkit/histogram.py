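"""Core containers: uniform time grids and TCSPC decay histograms.

All times are in nanoseconds everywhere in flimkit; raw hardware units
(TCSPC channel indices, macro-time ticks) are converted at the I/O
boundary and never leak past it.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GridMismatchError, InvalidGridError

#: relative tolerance on bin-spacing uniformity
GRID_RTOL = 1e-9

#: minimum number of bins for a usable grid
MIN_BINS = 8


@dataclass(frozen=True)
class TimeGrid:
    """A uniformly spaced grid of TCSPC bin centers.

    Parameters
    ----------
    bin_centers : ndarray
        Bin-center times in nanoseconds, strictly increasing and
        uniformly spaced to relative tolerance ``GRID_RTOL``.
    """

    bin_centers: np.ndarray

    def __post_init__(self):
        centers = np.asarray(self.bin_centers, dtype=float)
        if centers.ndim != 1 or centers.size < MIN_BINS:
            raise InvalidGridError(
                f"grid needs >= {MIN_BINS} bins, got shape {centers.shape}"
            )
        diffs = np.diff(centers)
        dt = diffs.mean()
        if dt <= 0:
            raise InvalidGridError("bin centers must be strictly increasing")
        if np.max(np.abs(diffs - dt)) > GRID_RTOL * dt:
            raise InvalidGridError(
                "bin spacing is not uniform to relative tolerance "
                f"{GRID_RTOL:g}"
            )
        object.__setattr__(self, "bin_centers", centers)

    @classmethod
    def from_window(cls, window_ns: float, n_bins: int) -> "TimeGrid":
        """Grid of ``n_bins`` bins covering ``[0, window_ns)``."""
        dt = window_ns / n_bins
        return cls(bin_centers=(np.arange(n_bins) + 0.5) * dt)

    @property
    def dt(self) -> float:
        """Bin width in ns."""
        return float(self.bin_centers[1] - self.bin_centers[0])

    @property
    def n_bins(self) -> int:
        return int(self.bin_centers.size)

    @property
    def span(self) -> tuple[float, float]:
        """(first edge, last edge) of the grid in ns."""
        half = 0.5 * self.dt
        return float(self.bin_centers[0] - half), float(self.bin_centers[-1] + half)

    @property
    def edges(self) -> np.ndarray:
        """Bin edges, length ``n_bins + 1``."""
        half = 0.5 * self.dt
        return np.concatenate(
            [self.bin_centers - half, [self.bin_centers[-1] + half]]
        )

    def contains(self, t: float) -> bool:
        lo, hi = self.span
        return lo <= t <= hi

    def is_same(self, other: "TimeGrid", rtol: float = GRID_RTOL) -> bool:
        return (
            self.n_bins == other.n_bins
            and np.allclose(self.bin_centers, other.bin_centers,
                            rtol=rtol, atol=rtol * self.dt)
        )

    def __eq__(self, other):
        return isinstance(other, TimeGrid) and self.is_same(other)


@dataclass(frozen=True)
class DecayHistogram:
    """Photon counts per micro-time bin on a uniform grid."""

    grid: TimeGrid
    counts: np.ndarray = field(repr=False)

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.shape != (self.grid.n_bins,):
            raise GridMismatchError(
                f"counts shape {counts.shape} does not match grid "
                f"({self.grid.n_bins} bins)"
            )
        if np.any(counts < 0):
            raise InvalidGridError("negative counts in histogram")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def peak_index(self) -> int:
        return int(np.argmax(self.counts))

    def truncated(self, n_bins_used: int) -> "DecayHistogram":
        """First ``n_bins_used`` bins as a new histogram (view semantics)."""
        if not MIN_BINS <= n_bins_used <= self.grid.n_bins:
            raise InvalidGridError(f"cannot truncate to {n_bins_used} bins")
        return DecayHistogram(
            grid=TimeGrid(self.grid.bin_centers[:n_bins_used]),
            counts=self.counts[:n_bins_used],
        )
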