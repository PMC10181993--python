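import numpy as np
import pytest

from vitivc import VarietyTruth, gen_cohort


@pytest.fixture
def truth() -> VarietyTruth:
    return VarietyTruth("Testvine", -2.5, 50.0)


@pytest.fixture
def sharp_truth() -> VarietyTruth:
    """Truth whose curve is fully intact at the -0.8 MPa reference pressure,
    so PLC computed against the first reading equals the model exactly."""
    return VarietyTruth("Steepvine", -3.0, 150.0)


@pytest.fixture
def small_cohort():
    varieties = [
        VarietyTruth("A", -2.0, 80.0, 0.1, 5.0),
        VarietyTruth("B", -3.0, 100.0, 0.1, 5.0),
    ]
    sweeps, truth_log = gen_cohort(varieties, n_plants_per_variety=3, noise_cv=0.03, seed=7)
    return sweeps, truth_log


@pytest.fixture
def variety_means():
    """Variety threshold means forming four clearly separated vulnerability
    groups (psi50 around -1.9, -2.5, -3.0, -3.4 MPa)."""
    import pandas as pd

    rows = []
    rng = np.random.default_rng(11)
    centers = {-1.9: 3, -2.5: 3, -3.0: 3, -3.4: 3}
    i = 0
    for c, n in centers.items():
        for _ in range(n):
            p50 = c + rng.normal(0, 0.02)
            rows.append(dict(variety=f"v{i}", psi12=p50 + 0.5, psi50=p50, psi88=p50 - 0.5))
            i += 1
    return pd.DataFrame(rows)
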