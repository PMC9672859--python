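"""FLIM image reconstruction, decay CSV and TIFF mask I/O.

A :class:`FlimImage` holds the per-pixel micro-time photon counts of a
scanned FLIM frame (or the sum of several frames).  It is reconstructed
from a TTTR event stream via line markers: photons between a line-start
and line-stop marker are assigned to columns by linear interpolation of
their macro time across the line.

Decay histograms travel as two-column CSV (``time_ns,counts``); label
masks as single-channel integer TIFF.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import (
    CsvFormatError,
    InvalidGridError,
    ReconstructionError,
)
from .histogram import DecayHistogram, TimeGrid
from .ptu import EventStream


@dataclass
class FlimImage:
    """Per-pixel micro-time photon counts on a uniform TCSPC grid."""

    data: np.ndarray = field(repr=False)  # (rows, cols, n_bins)
    dt: float  # micro-time bin width, ns

    def __post_init__(self):
        if self.data.ndim != 3:
            raise InvalidGridError("FlimImage data must be (rows, cols, bins)")
        if self.dt <= 0:
            raise InvalidGridError("dt must be > 0")

    @property
    def dims(self) -> tuple:
        return self.data.shape[:2]

    @property
    def n_tcspc_bins(self) -> int:
        return self.data.shape[2]

    @property
    def grid(self) -> TimeGrid:
        return TimeGrid((np.arange(self.n_tcspc_bins) + 0.5) * self.dt)

    @property
    def total_counts(self) -> int:
        return int(self.data.sum())

    def full_field_histogram(self) -> DecayHistogram:
        return DecayHistogram(grid=self.grid,
                              counts=self.data.sum(axis=(0, 1)))


@dataclass(frozen=True)
class MarkerConfig:
    """Marker-bit assignment of an acquisition (never hard-coded).

    Each field is the 4-bit mask identifying that marker in
    ``EventStream.marker_bits``; ``frame`` may be 0 when the stream has
    no frame markers (rows then wrap after ``dims[0]`` lines).
    """

    line_start: int = 0b0001
    line_stop: int = 0b0010
    frame: int = 0b0100


def reconstruct_flim_image(events: EventStream, marker_config: MarkerConfig,
                           dims: tuple, n_tcspc_bins: int,
                           micro_resolution_ns: float) -> tuple:
    """Assign photons to pixels from line markers.

    Photons between a line-start and its matching line-stop are mapped
    to columns by linear interpolation of macro time across the line;
    rows advance per line pair and wrap every ``dims[0]`` lines so
    repeated frames accumulate into one image.  Returns
    ``(FlimImage, n_discarded)`` where discarded photons are those
    outside any line interval.
    """
    rows, cols = dims
    starts = events.macro_time[(events.marker_bits & marker_config.line_start) != 0]
    stops = events.macro_time[(events.marker_bits & marker_config.line_stop) != 0]
    if len(starts) != len(stops):
        raise ReconstructionError(
            f"unbalanced line markers: {len(starts)} starts vs "
            f"{len(stops)} stops (line {min(len(starts), len(stops))})"
        )
    if len(starts) == 0:
        raise ReconstructionError("no line markers in stream")
    if np.any(stops <= starts):
        bad = int(np.nonzero(stops <= starts)[0][0])
        raise ReconstructionError(f"line {bad}: stop marker not after start")

    photons = events.photons()
    macro = photons.macro_time
    micro = photons.micro_time
    data = np.zeros((rows, cols, n_tcspc_bins), dtype=np.int64)

    # which line interval each photon falls into (if any)
    line_idx = np.searchsorted(starts, macro, side="right") - 1
    valid = line_idx >= 0
    valid[valid] &= macro[valid] <= stops[line_idx[valid]]
    valid &= micro < n_tcspc_bins

    li = line_idx[valid]
    frac = (macro[valid] - starts[li]) / (stops[li] - starts[li])
    col = np.minimum((frac * cols).astype(np.int64), cols - 1)
    row = li % rows
    np.add.at(data, (row, col, micro[valid]), 1)
    n_discarded = int(len(macro) - valid.sum())
    return FlimImage(data=data, dt=micro_resolution_ns), n_discarded


# ---------------------------------------------------------------------------
# CSV decay histograms


def read_decay_csv(path) -> DecayHistogram:
    """Read a two-column ``time_ns,counts`` CSV (header optional).

    Rows are sorted by time before validation, so shuffled files are
    accepted; non-uniform spacing or negative counts raise.
    """
    try:
        df = pd.read_csv(path, header=None, comment="#",
                         skip_blank_lines=True)
    except Exception as exc:  # pandas raises a zoo of parse errors
        raise CsvFormatError(f"{path}: cannot parse CSV ({exc})") from exc
    if df.shape[1] < 2:
        raise CsvFormatError(f"{path}: need two columns (time_ns, counts)")
    df = df.iloc[:, :2]
    # drop a header row if the first row is not numeric
    first = pd.to_numeric(df.iloc[0], errors="coerce")
    if first.isna().any():
        df = df.iloc[1:]
    df = df.apply(pd.to_numeric, errors="coerce")
    if df.isna().any().any():
        raise CsvFormatError(f"{path}: non-numeric values in data rows")
    if len(df) < 2:
        raise InvalidGridError(f"{path}: need at least 2 rows for a time grid")
    df = df.sort_values(df.columns[0])
    times = df.iloc[:, 0].to_numpy(dtype=float)
    counts = df.iloc[:, 1].to_numpy()
    if np.any(counts < 0):
        raise CsvFormatError(f"{path}: negative counts")
    grid = TimeGrid(bin_centers=times)  # validates uniform spacing
    return DecayHistogram(grid=grid, counts=counts)


def write_decay_csv(path, hist: DecayHistogram) -> None:
    """Write a histogram as ``time_ns,counts`` with a header row."""
    pd.DataFrame({"time_ns": hist.grid.bin_centers,
                  "counts": hist.counts}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# TIFF label masks


def read_mask_tiff(path) -> np.ndarray:
    """Read a single-channel integer label mask."""
    mask = tifffile.imread(path)
    if mask.ndim != 2:
        raise CsvFormatError(f"{path}: label mask must be single-channel 2-D")
    if not np.issubdtype(mask.dtype, np.integer):
        raise CsvFormatError(f"{path}: label mask must be integer-typed")
    return mask


def write_mask_tiff(path, mask: np.ndarray) -> None:
    tifffile.imwrite(Path(path), np.asarray(mask, dtype=np.uint16))
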