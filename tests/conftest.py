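import numpy as np
import pandas as pd
import pytest

import stratmr


@pytest.fixture
def small_cohort() -> pd.DataFrame:
    """A 5,000-person null cohort (no causal effects, no selection)."""
    return stratmr.simulate_cohort(stratmr.null_scenario(n=5_000, seed=42))


@pytest.fixture
def toy_cohort() -> pd.DataFrame:
    """A deterministic 20-row cohort for hand-checkable stratification."""
    rng = np.random.default_rng(7)
    g = rng.normal(size=20)
    x = 0.8 * g + rng.normal(size=20)
    return pd.DataFrame(
        {
            "id": np.arange(20),
            "instrument_score": g,
            "exposure": x,
            "age": rng.normal(57, 8, size=20),
            "sex": rng.integers(0, 2, size=20),
            "outcome_continuous": rng.normal(size=20),
            "outcome_binary": rng.integers(0, 2, size=20),
            "selected": np.ones(20, dtype=int),
        }
    )
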