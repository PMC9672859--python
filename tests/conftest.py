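"""Shared fixtures: grids and seeded synthetic decays."""
import numpy as np
import pytest

from flimkit.histogram import DecayHistogram, TimeGrid
from flimkit.simulate import SimulationTruth, bin_photons, sample_photons


@pytest.fixture
def grid() -> TimeGrid:
    """Standard 12.5 ns / 250 bin TCSPC grid."""
    return TimeGrid.from_window(12.5, 250)


def make_decay(seed: int, *, n_photons: int = 10_000, tau_signal: float = 2.5,
               tau_auto: float = 0.4, fraction_auto: float = 0.0,
               fraction_background: float = 0.0, irf_mu: float = 1.0,
               irf_sigma: float = 0.1, overflow: str = "drop") -> DecayHistogram:
    """Seeded synthetic decay histogram on the standard grid."""
    truth = SimulationTruth(
        tau_signal=tau_signal, tau_auto=tau_auto, fraction_auto=fraction_auto,
        fraction_background=fraction_background, irf_mu=irf_mu,
        irf_sigma=irf_sigma, n_photons=n_photons, overflow=overflow)
    times = sample_photons(truth, np.random.default_rng(seed))
    return bin_photons(times, truth.grid)


@pytest.fixture
def mono_hist_1e5() -> DecayHistogram:
    """High-count mono decay (tau = 2.5 ns) with known truth."""
    return make_decay(1, n_photons=100_000)
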