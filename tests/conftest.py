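import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def toy_ct_matrix():
    """3 genes x 4 samples with distinct variability per gene."""
    return pd.DataFrame(
        {
            "s1": [20.0, 22.0, 25.0],
            "s2": [20.5, 22.5, 24.0],
            "s3": [19.5, 21.5, 26.5],
            "s4": [20.2, 22.2, 23.8],
        },
        index=["gA", "gB", "gC"],
    )


@pytest.fixture
def equal_efficiencies():
    return pd.Series({"gA": 2.0, "gB": 2.0, "gC": 2.0}, name="efficiency")
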