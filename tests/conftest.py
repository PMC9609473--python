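import numpy as np
import pytest

from doxrelease import ExperimentCondition, RateConstants


@pytest.fixture
def neutral_310K_constants() -> RateConstants:
    """Published pair at 310 K, pH 7, 3.9 mol% AA, 1e-2 g/mL."""
    return RateConstants(k1=0.0165, k_minus1=0.153)


@pytest.fixture
def acidic_310K_constants() -> RateConstants:
    """Published pH 4 pair (the high-release regime, xi_inf > 0.5)."""
    return RateConstants(k1=0.123, k_minus1=0.093)


@pytest.fixture
def neutral_condition() -> ExperimentCondition:
    return ExperimentCondition(
        temperature=310.0, pH=7.0, x_aa=0.039, copolymer_conc=1e-2, label="neutral"
    )


@pytest.fixture
def temperature_series():
    """Published (T, k1) and (T, k_minus1) series, 278-323 K."""
    T = [278.0, 298.0, 310.0, 323.0]
    k1 = [2.80e-3, 1.27e-2, 1.65e-2, 3.52e-2]
    km1 = [0.119, 0.137, 0.153, 0.166]
    return list(zip(T, k1)), list(zip(T, km1))


@pytest.fixture
def default_times() -> np.ndarray:
    return np.arange(0.0, 48.0 + 1e-9, 2.0)
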