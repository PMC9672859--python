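# Methods

This note documents the statistical model, the numerical choices, and
the synthetic data behind flimkit's tests — including what the tests
do and do not demonstrate about real instrument data.

## Decay model and likelihood

The measured TCSPC histogram is modelled as one or two exponential
decays convolved with the instrument response. The IRF is a narrow
Gaussian with centre μ and width σ (both ns), or a measured IRF
histogram normalized to unit sum on the same grid. In convolution mode
the exponential always starts at the grid origin and the IRF carries
the time shift; fitting both a decay origin and μ would leave the model
unidentifiable (only their difference matters), so the pair is
collapsed by construction.

The fit objective is the Poisson negative log-likelihood
`Σ (m_i − n_i ln m_i)` with the `ln n_i!` constant dropped. Expected
values are clamped at ε = 1e-12 before the logarithm (a model that
predicts exactly zero where a photon landed would otherwise produce an
infinite objective). Gaussian/χ² fitting would be adequate at high
counts but is measurably biased in the few-photon-per-bin regime this
package targets, which is the reason for the Poisson choice.

With two components the shorter lifetime is, by convention, the
autofluorescence component; the optimizer enforces
τ_signal ≥ τ_auto so the labels cannot swap mid-fit.

### Discretization

The convolution is discrete: the exponential is averaged exactly over
each grid cell (this removes the half-bin time shift and O(dt) weight
error that point-sampling a function with a jump at t = 0 would
introduce), the Gaussian kernel is evaluated at bin centers and
renormalized to unit sum (total counts then do not depend on the σ/dt
ratio or edge truncation), and the product is convolved via FFT with
zero-padding to the next power of two ≥ 2·n_bins so circular
wrap-around cannot corrupt the rising edge. The remaining quadrature
error is O((dt/σ)²) and is largest on the deep rising edge; at
dt = σ/200 the curve agrees with the closed-form exponentially modified
Gaussian to better than 1e-4 everywhere the curve exceeds 1e-4 of its
peak (verified over a 27-point lattice by `benchmarks.convolution_agreement`).

### Optimization

The model is linear in the amplitudes and the NLL is convex in them,
so amplitudes are profiled out at every objective evaluation by a
monotone multiplicative (EM) update — exact in one step for one
component, geometric convergence for two, warm-started along the
optimizer path. The outer search over lifetimes and (μ, σ) is
Nelder-Mead on log-transformed scale parameters (positivity by
construction), multistarted with lifetime perturbations ×{1, 0.5, 2}
and restarted once from its own solution (a stalled simplex otherwise
occasionally leaves ~0.5% of the counts in a spurious component). Ties
between starts are broken toward the smaller signal lifetime.
Everything is deterministic given the inputs; repeated fits are
bit-identical.

Initialization is moment-based: μ₀ at the peak bin, σ₀ from the
rising-edge half-width at half-maximum divided by 1.177, τ₀ from the
mean arrival time after the peak. Domain floors reject lifetimes below
dt/2 and σ below dt/10 — sub-bin time constants are unresolvable on
the grid and only ever appear as degenerate likelihood spikes under
model misspecification.

## Endpoint selection

Uniform background (scattered light) accumulates across the whole
window and, if included, drags fitted lifetimes upward. The endpoint —
the last bin included in the fit — is therefore treated as a fit
variable: candidates from (peak + 24 bins) to the full range are swept
on a 16-bin stride with ±16-bin local refinement, each candidate refit
(warm-started from its neighbour) and scored.

The default score is the Poisson deviance per residual degree of
freedom, D/(N−k). The dof correction matters: without it the criterion
is biased low at short ranges, where the k parameters absorb a larger
share of the points. Selection follows an acceptability rule: if any
candidate range scores within one standard error (√(2/dof)) of 1 — the
asymptotic expectation when the model describes the data — the longest
such range wins, so clean decays are never cut merely because the
criterion fluctuates; if no range is acceptable, the minimum wins,
which in simulation cuts within a few bins of where background begins
to dominate. The sweep trace (endpoint, NLL, criterion) is retained on
the result for plotting.

A literal alternative — maximize NLL/√N over truncations — is kept
selectable as `endpoint_criterion="nll_sqrt"`. With the sign
convention of the NLL above it degenerates: simulation shows it selects
the full range whether or not background is present (high-count bins
dominate the cumulative NLL so strongly that tail bins never move the
ratio), defeating the purpose of cutting before background corrupts the
fit. The deviance form is the default for that reason; the simulation
suite (`benchmarks.endpoint_selection`) confirms the default cuts
before background dominates and leaves clean data uncut.

## Model-order selection

`auto` fits both orders at the selected endpoint and keeps the
bi-exponential only if (i) each amplitude fraction ≥ 1%, (ii)
τ_signal/τ_auto ≥ 1.5, and (iii) BIC on the Poisson likelihood —
penalizing the two extra parameters by ln N each — favors it. The
fraction and separation floors catch the two degenerate bi solutions
(an empty component; two copies of the same lifetime) that a pure
likelihood comparison cannot.

## Two-stage segment analysis

Stage 1 pools every photon in the field of view across all timepoints
and fits the full convolution model with automatic order selection,
yielding τ_auto, μ, σ. Autofluorescence is endogenous and unrelated to
the sensor, so using non-segmented pixels maximizes the photons behind
the hardest part of the fit. Stage 2 freezes those three values and
fits each segment's pooled histogram for τ_signal and the two
amplitudes only — a one-dimensional outer search after amplitude
profiling. When the field fit selects mono, segments are fit mono with
the IRF frozen.

Defaults: a segment needs ≥ 1000 photons (3-parameter Poisson fits are
empirically unstable below that in the simulation suite); at most 15
segments per image are analysed, chosen by descending photon count
(mirroring the acquisition practice of targeting ~15 clear nuclei, and
bounding runtime); QC rejects unconverged fits, lifetimes outside
[0.1, 10] ns, and fit windows under 32 bins, each with a logged reason.
Per-experiment pooling divides lifetimes by the experiment mean
(`normalize_group`), making each experiment's mean exactly 1.

## Shape metrics and axis splitting

Segments come from integer label masks; connected components sharing a
label are merged. Shape metrics are the image-moment ellipse
(normalized second central moments, axis length = 4√λ): aspect ratio =
major/minor, roundness = minor/major, orientation from the image row
axis in (−π/2, π/2]. The isoperimetric ratio 4πA/P² is available as an
alternative roundness but is not the default — the axis ratio is the
quantity that generalizes to length/width comparisons. Envelope pixels
split into long-axis and short-axis arcs at ±45° around the major axis:
a symmetric, parameter-free rule giving equal angular coverage. Below
aspect ratio 1.05 the axes are barely defined and the split warns (but
still returns a partition).

## PTU ingestion

The reader handles the PTU tagged header (all scalar tag types plus
strings) and PicoHarp T3 records — 16-bit sync counter, 12-bit
micro-time, overflow records extending macro time, 4-bit external
markers. Pixel assignment uses line markers only: photons between a
line-start and line-stop marker are placed in columns by linear
interpolation of macro time across the line, rows advance per line and
wrap per frame, frames accumulate. Marker-bit meanings are
configuration (`MarkerConfig`), never hard-coded, since acquisition
software conventions vary. All times are converted to ns at this
boundary; nothing downstream sees hardware ticks. HydraHarp/TimeHarp
record layouts are not implemented; unknown record types fail loudly
with the type code.

## Synthetic data: what it emulates, what it does not

The generator draws each photon's component (autofluorescence, signal,
or uniform background) from the configured fractions, adds an
exponential delay with the component's lifetime, and jitters by the
Gaussian IRF. Default truth values — τ_auto 0.4 ns, τ_signal 2.8 ns,
σ 0.1 ns, μ 1.0 ns, 12.5 ns window at 250 bins — are plausible for an
mTFP-donor sensor on an 80 MHz-class TCSPC system; they are fixture
choices, not measured values. Scenes place elliptical-ring ROIs
(standing in for nuclear envelopes) on a dark or autofluorescent
field, split each photon budget exactly across six timepoints, and can
be exported as mask TIFF + truth CSV + per-segment decay CSVs +
minimal PTU files per timepoint.

Photons past the window **wrap modulo the window by default**,
mimicking repetition-rate wrap-around of long-lived emission.  The
fitted model, like the original fitting approach it implements, assumes
the decay is complete within the window — it puts no mass before the
IRF rise, so the wrapped pre-rise pedestal is unmodelled. Two
consequences, both measured in the suite: absolute lifetimes from
wrapped scenes carry a small negative bias (~2-3% at these settings)
while rank order and contrasts are preserved; and at very high counts
(≥1e5 photons) the pedestal can push an unconstrained bi fit toward a
degenerate near-floor lifetime with inflated σ. Parameter-recovery
studies therefore run the generator in `overflow="drop"` mode (photons
outside the window discarded), which matches the fitted model exactly
and is the regime in which recovery tolerances are meaningful;
scene-level studies (conservation, rank order, end-to-end pipeline)
keep the wrap default. Passing recovery tests under `drop` shows the
estimator is correct for its own model; it does not bound the
wrap-around bias on real hardware, which depends on the repetition
period relative to the lifetime.

Not modelled at all: detector afterpulsing, dead time, pile-up, and
optical blur of the ring images.

## Study sizes

The acceptance studies use: a 27-point convolution lattice; 50 seeds at
1e4 photons (plus 20-seed series at 1e3/1e4/1e5) for recovery; 5 seeds
× 30 segments at 2e3 photons against a 5e5-photon calibration field for
the two-stage comparison (both arms fit the full range — no background
is simulated there, so endpoint sweeps would only add noise and
runtime); 20 seeds with 5%-of-peak background plus 5 clean seeds for
endpoint selection; 40 runs per class at 1e5 photons for model order;
and a 10-ring gradient scene at 1e4 photons/ring end to end. The whole
set completes in a few minutes on one CPU.

## Known limitations

* No constant-background term in the fitted model; background is
  handled by endpoint cutting only, as in the procedure this package
  implements. A background amplitude would be a natural extension.
* No incomplete-decay (wrap-around) correction; see above.
* Endpoint criterion values are computed per candidate from refits on a
  16-bin stride; pathological data whose deviance profile oscillates
  faster than the stride could be mis-cut.
* The 2D axis split inherits the usual caveat of planar sections
  through 3D objects: oblique sections underestimate true elongation.
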