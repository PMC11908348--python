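import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import lucidomics as lo

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort, prepared (imputed + log2 exposure)."""
    cohort, layers, truth = lo.generate_cohort(seed=11)
    return lo.prepare_cohort(cohort), layers, truth


@pytest.fixture(scope="session")
def standardized_layers(default_cohort):
    _, layers, _ = default_cohort
    return {name: lo.standardize_features(layer) for name, layer in layers.items()}


def make_layer(Z: np.ndarray, name: str = "metabolome", **meta) -> lo.OmicsLayer:
    """Wrap a bare matrix as an OmicsLayer with optional QC metadata."""
    df = pd.DataFrame(
        Z,
        index=[f"S{i:04d}" for i in range(len(Z))],
        columns=[f"f{j}" for j in range(Z.shape[1])],
    )
    series = {
        k: pd.Series(v, index=df.columns) for k, v in meta.items() if v is not None
    }
    return lo.OmicsLayer(name=name, values=df, **series)
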