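"""Self-contained validation studies of the whole toolchain.

Each function generates its own synthetic inputs with known ground
truth (seeded), runs the relevant part of the package from scratch, and
returns summary metrics.  The studies double as the acceptance suite:
``scripts/acceptance.py`` reports their numbers and the test-suite
asserts thresholds on them.

Parameter-recovery studies use the generator's ``drop`` overflow mode
(photons outside the TCSPC window discarded) so the generative model
matches the fitted model exactly; scene-level studies keep the
default repetition-rate wrap-around.  See docs/methods.md.
"""
from __future__ import annotations

import itertools

import numpy as np
from scipy.stats import spearmanr

from .decay_model import (
    CompositeDecayModel,
    ExpComponent,
    GaussianIrf,
    exp_mod_gauss,
    gaussian_kernel,
    model_curve,
)
from .fitting import FitConfig, choose_endpoint, fit_decay
from .histogram import DecayHistogram, TimeGrid
from .io import read_decay_csv, write_decay_csv
from .pipeline import QcThresholds, calibrate_field, fit_segment, run_flimseg
from .ptu import EventStream, read_ptu, write_ptu
from .segmentation import SegmentRecord, ellipse_shape, split_envelope_axes
from .simulate import (
    SimulationTruth,
    bin_photons,
    default_gradient_scene,
    sample_histogram,
    sample_photons,
    simulate_scene,
)


def _child_seeds(seed: int, n: int, salt: int) -> list:
    """Deterministic sub-seeds below 2**31."""
    rng = np.random.default_rng([seed, salt])
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


# ---------------------------------------------------------------------------
# 1. convolution correctness


def convolution_agreement() -> dict:
    """FFT model curve vs the closed-form EMG and O(N^2) convolution.

    The EMG lattice covers tau x sigma x mu = {0.3,1.2,4} x
    {0.05,0.15,0.3} x {6,10,20} sigma at dt = sigma/200, compared over
    bins carrying >= 1e-4 of the peak intensity.
    """
    worst_emg = 0.0
    for tau, sigma, mu_mult in itertools.product(
            [0.3, 1.2, 4.0], [0.05, 0.15, 0.3], [6.0, 10.0, 20.0]):
        mu = mu_mult * sigma
        dt = sigma / 200
        n = int(np.ceil((mu + 8 * tau) / dt))
        grid = TimeGrid((np.arange(n) + 0.5) * dt)
        model = CompositeDecayModel((ExpComponent(1.0, tau),),
                                    irf=GaussianIrf(mu, sigma))
        curve = model_curve(model, grid)
        closed = exp_mod_gauss(grid.bin_centers, 1.0, tau, mu, sigma)
        mask = closed > closed.max() * 1e-4
        worst_emg = max(worst_emg, float(np.max(
            np.abs(curve[mask] - closed[mask]) / closed[mask])))

    # FFT vs direct nested-loop discrete convolution
    grid = TimeGrid.from_window(6.0, 120)
    rng = np.random.default_rng(12345)
    decay = rng.random(grid.n_bins)
    irf = GaussianIrf(mu=1.0, sigma=0.2)
    from .decay_model import convolve_irf

    fft_curve = convolve_irf(decay, irf, grid)
    kernel = gaussian_kernel(irf, grid)
    direct = np.zeros(grid.n_bins)
    for j in range(grid.n_bins):
        for k in range(j + 1):
            direct[j] += decay[k] * kernel[j - k]
    worst_direct = float(np.max(np.abs(fft_curve - direct)
                                / np.maximum(direct, 1e-300)))
    return {"emg_max_rel_err": worst_emg,
            "direct_conv_max_rel_err": worst_direct,
            "n_lattice_points": 27}


# ---------------------------------------------------------------------------
# 2. Poisson-MLE parameter recovery


def _recovery_hist(seed: int, n_photons: int) -> DecayHistogram:
    truth = SimulationTruth(tau_signal=2.5, fraction_auto=0.0,
                            irf_sigma=0.1, n_photons=n_photons,
                            overflow="drop")
    return sample_histogram(truth, np.random.default_rng(seed))


def mono_recovery(seed: int, n_seeds: int = 50,
                  budgets: tuple = (1_000, 10_000, 100_000),
                  n_seeds_budget: int = 20) -> dict:
    """Median relative error of tau-hat for a mono decay (tau = 2.5 ns)."""
    config = FitConfig(model_order="mono", endpoint_policy="full")
    errs = []
    for s in _child_seeds(seed, n_seeds, salt=2):
        res = fit_decay(_recovery_hist(s, 10_000), config)
        errs.append(abs(res.signal_lifetime - 2.5) / 2.5)
    out = {"median_rel_err_pct_1e4": float(np.median(errs) * 100),
           "n_seeds": n_seeds}
    # separate, equal-n series for the error-vs-photon-budget comparison
    for budget in budgets:
        errs = []
        for s in _child_seeds(seed, n_seeds_budget, salt=3):
            res = fit_decay(_recovery_hist(s, budget), config)
            errs.append(abs(res.signal_lifetime - 2.5) / 2.5)
        key = f"monotone_rel_err_pct_{budget:.0e}".replace("e+0", "e")
        out[key] = float(np.median(errs) * 100)
    return out


# ---------------------------------------------------------------------------
# 3. two-stage decoupling benefit


def two_stage_benefit(seed: int, n_seeds: int = 5,
                      n_segments: int = 30) -> dict:
    """Two-stage (calibrated) segment fits vs joint 6-parameter fits.

    Field truth: tau_signal 2.2 ns, tau_auto 0.4 ns, 25% fast fraction;
    5e5-photon calibration field, 2e3-photon segments.
    """
    kwargs = dict(tau_signal=2.2, tau_auto=0.4, fraction_auto=0.25,
                  overflow="drop")
    cfg = FitConfig(endpoint_policy="full", min_counts=100)
    two_stage, joint = [], []
    for s in _child_seeds(seed, n_seeds, salt=5):
        rng = np.random.default_rng(s)
        field = sample_histogram(
            SimulationTruth(n_photons=500_000, **kwargs), rng)
        calib = calibrate_field(field, cfg)
        for _ in range(n_segments):
            hist = sample_histogram(
                SimulationTruth(n_photons=2_000, **kwargs), rng)
            two_stage.append(fit_segment(hist, calib, cfg).signal_lifetime)
            joint.append(fit_decay(hist, FitConfig(
                model_order="bi", endpoint_policy="full",
                min_counts=100)).signal_lifetime)
    rmse = lambda v: float(np.sqrt(np.mean((np.asarray(v) - 2.2) ** 2)))
    return {"two_stage_rmse_ns": rmse(two_stage),
            "joint_rmse_ns": rmse(joint),
            "n_segments": len(two_stage)}


# ---------------------------------------------------------------------------
# 4. endpoint selection


def endpoint_selection(seed: int, n_seeds: int = 20,
                       background_of_peak: float = 0.05) -> dict:
    """Endpoint sweep vs full-range fits with and without background."""
    config = FitConfig(model_order="mono")
    full_cfg = FitConfig(model_order="mono", endpoint_policy="full")
    sel_err, full_err = [], []
    for s in _child_seeds(seed, n_seeds, salt=7):
        rng = np.random.default_rng(s)
        hist = _recovery_hist(s, 10_000)
        bg = rng.poisson(background_of_peak * hist.counts.max(),
                         hist.grid.n_bins)
        hist = DecayHistogram(hist.grid, hist.counts + bg)
        _, res = choose_endpoint(hist, config)
        sel_err.append(abs(res.signal_lifetime - 2.5))
        full_err.append(abs(fit_decay(hist, full_cfg).signal_lifetime - 2.5))
    nobg_fracs = []
    for s in _child_seeds(seed, 5, salt=8):
        hist = _recovery_hist(s, 10_000)
        n, _ = choose_endpoint(hist, config)
        nobg_fracs.append(n / hist.grid.n_bins)
    return {"bg_mean_abs_err_selected_ns": float(np.mean(sel_err)),
            "bg_mean_abs_err_full_ns": float(np.mean(full_err)),
            "nobg_min_endpoint_fraction_pct": float(min(nobg_fracs) * 100),
            "n_seeds": n_seeds}


# ---------------------------------------------------------------------------
# 5. model-order selection


def model_order_selection(seed: int, n_runs: int = 40) -> dict:
    """Fraction of correct mono/bi decisions at 1e5 photons."""
    config = FitConfig(model_order="auto", endpoint_policy="full")
    mono_ok = 0
    for s in _child_seeds(seed, n_runs, salt=11):
        hist = sample_histogram(SimulationTruth(
            tau_signal=2.0, fraction_auto=0.0, n_photons=100_000,
            overflow="drop"), np.random.default_rng(s))
        mono_ok += fit_decay(hist, config).model_order_used == "mono"
    bi_ok = 0
    for s in _child_seeds(seed, n_runs, salt=12):
        hist = sample_histogram(SimulationTruth(
            tau_signal=2.8, tau_auto=0.4, fraction_auto=0.3,
            n_photons=100_000, overflow="drop"), np.random.default_rng(s))
        bi_ok += fit_decay(hist, config).model_order_used == "bi"
    return {"mono_correct_pct": 100.0 * mono_ok / n_runs,
            "bi_correct_pct": 100.0 * bi_ok / n_runs,
            "n_runs": n_runs}


# ---------------------------------------------------------------------------
# 6. photon conservation


def photon_conservation(seed: int) -> dict:
    """Exact integer conservation through binning, segment aggregation
    and six-timepoint summation on a simulated scene."""
    from .pipeline import aggregate_timepoints
    from .segmentation import label_mask

    scene = default_gradient_scene(n_rings=6, photons_per_ring=3_000)
    result = simulate_scene(scene, np.random.default_rng(seed))
    discrepancies = []
    # binning conserves the photon list
    truth = SimulationTruth(n_photons=5_000)
    times = sample_photons(truth, np.random.default_rng(seed + 1))
    discrepancies.append(bin_photons(times, truth.grid).total - len(times))
    # six-timepoint full-field sum
    records = label_mask(result.mask)
    records, full = aggregate_timepoints(result.images, records)
    discrepancies.append(
        full.total - sum(img.total_counts for img in result.images))
    # segment aggregation vs generator budget
    discrepancies.append(
        sum(r.photon_count for r in records)
        - int(result.truth_table.n_photons.sum()))
    return {"max_abs_count_discrepancy": int(np.max(np.abs(discrepancies)))}


# ---------------------------------------------------------------------------
# 7. shape metrics


def shape_metrics(seed: int) -> dict:
    """Aspect ratio of rasterized references + axis-split partition."""
    from skimage.draw import disk, ellipse

    def record_from(shape_fn, *args, **kwargs):
        img = np.zeros((121, 121), dtype=np.uint8)
        rr, cc = shape_fn(*args, shape=img.shape, **kwargs)
        img[rr, cc] = 1
        return ellipse_shape(SegmentRecord(label=1, pixels=np.argwhere(img)))

    aspects = [record_from(ellipse, 60, 60, 20, 10, rotation=rot).aspect_ratio
               for rot in np.deg2rad([0, 30, 60, 115])]
    circle = record_from(disk, (60, 60), 25).aspect_ratio

    rng = np.random.default_rng(seed)
    violations = 0
    for _ in range(25):
        outer = np.zeros((121, 121), dtype=bool)
        a = rng.uniform(15, 35)
        b = a * rng.uniform(0.4, 0.95)
        rot = rng.uniform(-1.5, 1.5)
        rr, cc = ellipse(60, 60, a, b, shape=outer.shape, rotation=rot)
        outer[rr, cc] = True
        rr, cc = ellipse(60, 60, a - 3, b - 3, shape=outer.shape, rotation=rot)
        outer[rr, cc] = False
        rec = ellipse_shape(SegmentRecord(label=1, pixels=np.argwhere(outer)))
        long_pix, short_pix = split_envelope_axes(rec)
        union = {tuple(p) for p in long_pix} | {tuple(p) for p in short_pix}
        if (len(long_pix) + len(short_pix) != rec.n_pixels
                or union != {tuple(p) for p in rec.pixels}):
            violations += 1
    return {"ellipse_aspect_ratio_worst": float(
                max(aspects, key=lambda a: abs(a - 2.0))),
            "circle_aspect_ratio": float(circle),
            "axis_partition_violations": violations}


# ---------------------------------------------------------------------------
# 8. end-to-end gradient scene


def pipeline_gradient(seed: int, n_rings: int = 10,
                      photons_per_ring: int = 10_000) -> dict:
    """Rank-order recovery of a monotone lifetime gradient."""
    scene = default_gradient_scene(n_rings=n_rings,
                                   photons_per_ring=photons_per_ring)
    result = simulate_scene(scene, np.random.default_rng(seed))
    table, _, _ = run_flimseg(result.images, result.mask, FitConfig(),
                              QcThresholds(min_counts=500),
                              target_segments=n_rings)
    truth = result.truth_table.rename(
        columns={"label": "segment_label", "tau_signal_ns": "tau_true"})
    merged = table.merge(truth[["segment_label", "tau_true"]],
                         on="segment_label")
    rho = spearmanr(merged.tau_signal_ns, merged.tau_true).statistic
    return {"spearman_rho": float(rho), "n_rings": int(len(merged))}


# ---------------------------------------------------------------------------
# 9. I/O round-trips


def io_roundtrips(seed: int, tmpdir, n_events: int = 10_000) -> dict:
    """PTU write->read identity and decay-CSV count exactness."""
    from pathlib import Path

    tmpdir = Path(tmpdir)
    rng = np.random.default_rng(seed)
    macro = np.sort(rng.integers(0, 2_000_000, size=n_events))
    events = EventStream(
        macro_time=macro,
        micro_time=rng.integers(0, 4096, size=n_events).astype(np.int64),
        channel=rng.integers(0, 4, size=n_events).astype(np.int64),
        marker_bits=np.zeros(n_events, dtype=np.int64))
    path = tmpdir / "roundtrip.ptu"
    write_ptu(path, events, resolution_ns=0.05, sync_period_ns=12.5)
    _, back = read_ptu(path)
    mismatches = int((back.macro_time != events.macro_time).sum()
                     + (back.micro_time != events.micro_time).sum()
                     + (back.channel != events.channel).sum())

    hist = _recovery_hist(seed, 20_000)
    csv_path = tmpdir / "roundtrip.csv"
    write_decay_csv(csv_path, hist)
    back_hist = read_decay_csv(csv_path)
    csv_diff = int(np.max(np.abs(back_hist.counts - hist.counts)))
    return {"ptu_roundtrip_mismatches": mismatches,
            "csv_max_count_diff": csv_diff,
            "n_events": n_events}
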