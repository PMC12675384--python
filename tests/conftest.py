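import numpy as np
import pytest

from podotherm import ThermoParams
from podotherm.synthetic import DEFAULT_REGION_TRUTH


@pytest.fixture
def thermo_params() -> ThermoParams:
    """Literature mean inputs for a 30-min walk at 1.25 m/s."""
    return ThermoParams(
        W_stride_kJ=-0.0034,
        m_foot_kg=1.17,
        c_foot_kJ_per_kgK=1.96,
        total_strides=1674,
        duration_min=30.0,
        W_bounds=(-0.0071, 0.00023),
        c_bounds=(1.31, 3.62),
    )


@pytest.fixture
def hallux_truth() -> dict:
    """Strongly S-shaped reference coefficients (hallux region)."""
    return dict(DEFAULT_REGION_TRUTH["hallux"])


@pytest.fixture
def walk_times() -> np.ndarray:
    """Photo schedule: every 5 min over a 30-min walk."""
    return np.arange(0.0, 31.0, 5.0)
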