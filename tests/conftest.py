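import numpy as np
import pandas as pd
import pytest

import larvaprint as lp


@pytest.fixture
def toy_trace():
    """Six-frame Δ-pixel trace with hand-computable bout structure."""
    return np.array([0.0, 3.0, 5.0, 0.0, 0.0, 2.0])


@pytest.fixture
def small_dataset():
    """2-well, 24 h, 1 Hz dataset on the default 14:10 schedule."""
    rng = np.random.default_rng(42)
    n = 86400
    vals = {
        "w1": np.where(rng.random(n) < 0.4, 0.0, rng.gamma(2.0, 5.0, n)),
        "w2": np.where(rng.random(n) < 0.6, 0.0, rng.gamma(2.0, 5.0, n)),
    }
    return lp.TrackingDataset(
        traces=pd.DataFrame(vals),
        groups=pd.Series({"w1": "wt", "w2": "mut"}),
        fps=1.0,
    )


@pytest.fixture(scope="session")
def planted_plate():
    """Small plate with a planted daytime-only effect (shared across tests)."""
    cfg = lp.PlateSimConfig(
        n_wells_per_group=12,
        duration_hours=24.0,
        group_effects={
            "wt": lp.GroupEffect(),
            "mut": lp.GroupEffect(day_amplitude_factor=1.5, day_bout_rate_factor=1.3),
        },
        seed=2024,
    )
    return lp.simulate_plate(cfg)
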