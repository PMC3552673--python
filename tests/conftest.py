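import numpy as np
import pandas as pd
import pytest

from cdtox import ExpressionStudy, SimulationConfig, simulate_study


@pytest.fixture
def toy_study() -> ExpressionStudy:
    """5 probes x 4 samples, one exposure block, hand-set calls."""
    probes = [f"p{i}" for i in range(1, 6)]
    samples = ["s0", "s9", "s27", "s45"]
    signal = pd.DataFrame(
        [
            [10.0, 20.0, 25.0, 50.0],   # rising
            [5.0, 5.0, 5.0, 5.0],       # constant
            [40.0, 30.0, 22.0, 11.0],   # falling
            [8.0, 9.0, 7.5, 8.2],       # noise
            [100.0, 90.0, 95.0, 105.0],  # noise, all absent
        ],
        index=probes,
        columns=samples,
    )
    calls = pd.DataFrame(
        [
            ["P", "P", "P", "P"],
            ["A", "P", "A", "A"],
            ["P", "P", "P", "M"],
            ["M", "M", "M", "M"],
            ["A", "A", "A", "A"],
        ],
        index=probes,
        columns=samples,
    )
    design = pd.DataFrame(
        {"time_days": [1.0, 1.0, 1.0, 1.0], "dose_uM": [0.0, 9.0, 27.0, 45.0]},
        index=pd.Index(samples, name="sample_id"),
    )
    return ExpressionStudy(signal=signal, calls=calls, design=design)


@pytest.fixture(scope="session")
def default_sim():
    """One default-config simulated study, shared across tests."""
    return simulate_study(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def null_config() -> dict:
    """Config fields that switch off every planted effect."""
    return dict(
        frac_pos_block1=0.0,
        frac_neg_block1=0.0,
        frac_pos_block2=0.0,
        frac_neg_block2=0.0,
        module_specs=(),
    )
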