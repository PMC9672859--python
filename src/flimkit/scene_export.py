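"""Write simulated scenes to disk in the formats the pipeline ingests.

A scene exports as: a 16-bit label-mask TIFF, a ground-truth CSV, one
pooled decay CSV per segment, and (optionally) one minimal PicoHarp T3
PTU file per timepoint, complete with line markers so the PTU path of
the pipeline can reconstruct the images.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np

from .io import FlimImage, MarkerConfig, write_decay_csv, write_mask_tiff
from .ptu import EventStream
from .ptu import write_ptu as _write_ptu_file
from .segmentation import attach_histograms, label_mask
from .simulate import SceneResult

#: macro-time length of one scan line, in sync periods
SYNCS_PER_LINE = 4096
#: idle gap between lines, in sync periods
LINE_GAP = 64


def image_to_events(image: FlimImage, markers: MarkerConfig) -> EventStream:
    """Serialize an image into a marker-framed TTTR event stream.

    Each row becomes a line-start marker, its photons (macro time
    placed by column), then a line-stop marker.
    """
    rows, cols = image.dims
    macro, micro, marker = [], [], []
    t = 0
    for r in range(rows):
        start, stop = t, t + SYNCS_PER_LINE
        macro.append(start)
        micro.append(0)
        marker.append(markers.line_start)
        row_data = image.data[r]
        cc, bb = np.nonzero(row_data)
        counts = row_data[cc, bb]
        if len(cc):
            pix_macro = start + 1 + ((cc + 0.5) / cols * (SYNCS_PER_LINE - 2))
            pix_macro = np.repeat(pix_macro.astype(np.int64), counts)
            order = np.argsort(pix_macro, kind="stable")
            macro.extend(pix_macro[order])
            micro.extend(np.repeat(bb, counts)[order])
            marker.extend(np.zeros(len(pix_macro), dtype=np.int64))
        macro.append(stop)
        micro.append(0)
        marker.append(markers.line_stop)
        t = stop + LINE_GAP
    macro = np.asarray(macro, dtype=np.int64)
    micro = np.asarray(micro, dtype=np.int64)
    marker = np.asarray(marker, dtype=np.int64)
    return EventStream(macro_time=macro, micro_time=micro,
                       channel=np.zeros(len(macro), dtype=np.int64),
                       marker_bits=marker)


def export_scene(result: SceneResult, outdir, write_ptu: bool = False,
                 markers: MarkerConfig = MarkerConfig()) -> dict:
    """Write a scene's mask, truth table, decay CSVs and optional PTUs.

    Returns a dict of the written paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    mask_path = outdir / "mask.tif"
    write_mask_tiff(mask_path, result.mask)
    paths["mask"] = mask_path

    truth_path = outdir / "truth.csv"
    result.truth_table.to_csv(truth_path, index=False)
    paths["truth"] = truth_path

    # pooled per-segment decay histograms
    pooled = FlimImage(
        data=sum(img.data for img in result.images), dt=result.images[0].dt)
    records = attach_histograms(label_mask(result.mask), pooled)
    for record in records:
        path = outdir / f"decay_segment_{record.label:03d}.csv"
        write_decay_csv(path, record.histogram)
        paths[f"decay_{record.label}"] = path

    if write_ptu:
        window_ns = result.images[0].dt * result.images[0].n_tcspc_bins
        for tp, image in enumerate(result.images):
            events = image_to_events(image, markers)
            path = outdir / f"timepoint_{tp:02d}.ptu"
            _write_ptu_file(path, events, resolution_ns=image.dt,
                            sync_period_ns=window_ns)
            paths[f"ptu_{tp}"] = path
    return paths
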