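# flimkit

Poisson maximum-likelihood analysis of fluorescence lifetime imaging
(FLIM) data, built for the low-photon regime of in-vivo FRET tension
sensing.

Measuring forces with genetically encoded FRET tension sensors in live
tissue means reading tiny shifts of a donor fluorophore's excited-state
lifetime out of noisy time-correlated single photon counting (TCSPC)
histograms. Two noise sources dominate in vivo: a fast endogenous
autofluorescence decay riding on the instrument response, and uniform
background/scattered light that accumulates in the late bins of the
TCSPC window. flimkit implements a fitting strategy designed for
exactly this regime, together with the segmentation, I/O and
simulation scaffolding needed to run it on whole imaging sessions —
or to validate every stage against synthetic data with known ground
truth.

## The model

A measured decay histogram is modelled as exponential decays convolved
with a Gaussian instrument response function (IRF):

    f(t) = A_auto exp(-t/τ_auto) + A_signal exp(-t/τ_signal)
    g(t) = Gaussian(μ, σ)
    m(t) = (f ⊗ g)(t)

fit by minimizing the Poisson negative log-likelihood over the included
bins,

    NLL = Σ_i [ m_i − n_i ln m_i ]

which is the correct counting statistic when photons are scarce.
Convolution runs over zero-padded FFTs; amplitudes are profiled out
exactly at every optimizer step (the NLL is convex in them), so only
the lifetimes and (μ, σ) are searched.

Three automatic decisions remove per-curve hand tuning:

* **Endpoint selection** — the last bin included in the fit is treated
  as a fit variable: candidate endpoints are swept, each refit and
  scored by the Poisson deviance per residual degree of freedom, and
  the data are cut where background light starts to drag the fit away
  from the signal value.
* **Model order** — mono- vs bi-exponential is chosen by amplitude
  fraction, lifetime separation, and a BIC penalty on the two extra
  parameters.
* **Two-stage decoupling** — τ_auto, μ and σ are calibrated once on the
  *full field of view* (autofluorescence is unrelated to the sensor, so
  every pixel contributes) and then frozen in per-segment fits, leaving
  only the signal lifetime and two amplitudes free. Segments with a
  couple of thousand photons become fittable where a joint 6-parameter
  fit is unstable.

The segmented pipeline ingests PicoQuant PTU event streams (PicoHarp
T3) plus TIFF label masks, pools photons per nuclear-envelope segment
across timepoints (six by default), computes image-moment ellipse shape
metrics (aspect ratio / roundness, long- vs short-axis arcs), fits
every segment, applies quality-control filters with logged rejection
reasons, and writes a results CSV.

## Worked example

Simulate a six-timepoint scene of ten elliptical nuclear-envelope rings
carrying a monotone lifetime gradient, then run the full two-stage
pipeline on it:

```python
import numpy as np
from flimkit import FitConfig, QcThresholds, run_flimseg
from flimkit.simulate import default_gradient_scene, simulate_scene

scene = default_gradient_scene(n_rings=10, photons_per_ring=10_000)
result = simulate_scene(scene, np.random.default_rng(3))
table, segments, calib = run_flimseg(result.images, result.mask,
                                     FitConfig(), QcThresholds(min_counts=500))
print(table[["segment_label", "tau_signal_ns", "photon_count",
             "qc_accepted"]].head(3).to_string(index=False))
```

```
 segment_label  tau_signal_ns  photon_count  qc_accepted
             1       1.931277         10000         True
             2       2.060660         10000         True
             3       2.186425         10000         True
```

Ring 1 was simulated with a 2.0 ns signal lifetime, ring 2 with 2.13 ns,
ring 3 with 2.27 ns: each recovered lifetime tracks its ground truth to
within a few percent from only 10,000 photons per ring, and the rank
order of the whole ten-ring gradient is recovered exactly (Spearman
ρ = 1.0). The small systematic shortfall (~3%) is the un-modelled
repetition-rate wrap-around the generator applies by default; see
`docs/methods.md`.

Single curves work the same way from the shell:

```bash
flimkit simulate --outdir scene --n-rings 3 --seed 7 --write-ptu
flimkit fit scene/decay_segment_001.csv --model auto
flimkit pipeline scene/timepoint_*.ptu --mask scene/mask.tif --rows 96 --cols 96
```

or as a scikit-learn style estimator:

```python
from flimkit import DecayFitter
fitter = DecayFitter(model_order="auto").fit(hist)   # DecayHistogram or (t, counts)
fitter.tau_signal_, fitter.n_bins_used_, fitter.model_order_
```

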