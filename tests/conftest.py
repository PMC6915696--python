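import numpy as np
import pytest

from polyqlen import (
    DoseResponseSeries,
    FourPLParams,
    SimulationConfig,
    build_calibration,
    fit_standard_series,
    simulate_standard_curves,
)


@pytest.fixture(scope="session")
def noiseless_config() -> SimulationConfig:
    return SimulationConfig(seed=1, noise_cv=0.0)


@pytest.fixture(scope="session")
def noisy_config() -> SimulationConfig:
    return SimulationConfig(seed=7, noise_cv=0.05)


@pytest.fixture(scope="session")
def noiseless_calibration(noiseless_config):
    """Calibrator + training arrays fitted on exact synthetic standards."""
    polyq = fit_standard_series(simulate_standard_curves(noiseless_config, "polyq"))
    total = fit_standard_series(simulate_standard_curves(noiseless_config, "total"))
    return build_calibration(polyq, total)


@pytest.fixture()
def fourpl_series() -> DoseResponseSeries:
    """Exact 4PL data at 8 concentrations, duplicate wells."""
    params = FourPLParams(bottom=100.0, top=10000.0, ec50=500.0, hillslope=1.0)
    conc = np.repeat([5, 15, 50, 150, 500, 1500, 5000, 15000], 2).astype(float)
    from polyqlen import evaluate_four_pl

    sig = np.array([evaluate_four_pl(params, c) for c in conc])
    series = DoseResponseSeries.from_arrays(conc, sig, sample_id="exact")
    series.true_params = params
    return series
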