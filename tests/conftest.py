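import numpy as np
import pandas as pd
import pytest

from aukcalls import PARAMETER_COLUMNS, SimConfig, generate_dataset


@pytest.fixture(scope="session")
def default_feature_dataset():
    """One default-condition feature-tier dataset, shared across tests."""
    return generate_dataset(SimConfig(seed=11), tier="feature")


@pytest.fixture()
def zero_noise_config():
    return SimConfig(
        sigma_individual={k: 0.0 for k in PARAMETER_COLUMNS},
        sigma_residual={k: 0.0 for k in PARAMETER_COLUMNS},
        call_count_model=3,
        seed=0,
    )


@pytest.fixture()
def small_balanced_features():
    """Tiny deterministic feature table: 4 individuals x 6 calls."""
    rng = np.random.default_rng(123)
    rows = []
    for ctx, inds in [("begging", ["N_01", "N_02"]), ("handling", ["H_01", "H_02"])]:
        for ind in inds:
            b = rng.normal(0, 1, size=len(PARAMETER_COLUMNS))
            for j in range(6):
                vals = b + rng.normal(0, 0.5, size=len(PARAMETER_COLUMNS))
                if ctx == "begging":
                    vals = vals + 2.0
                rows.append({
                    "call_id": f"{ind}_c{j}", "individual_id": ind, "context": ctx,
                    **dict(zip(PARAMETER_COLUMNS, vals)),
                })
    return pd.DataFrame(rows)
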