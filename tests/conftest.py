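import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from bdfunc.signatures import BidirectionalSignature

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def small_signature() -> BidirectionalSignature:
    return BidirectionalSignature.from_gene_lists(
        "SIG", [f"A{i}" for i in range(5)], [f"I{i}" for i in range(5)]
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)


@pytest.fixture
def diff_table() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene": ["G1", "G2", "G3", "G4", "G5"],
            "fold_change": [3.0, -3.0, 3.0, 2.0, -1.2],
            "p_value": [0.001, 0.001, 0.001, 0.001, 0.001],
            "fdr": [0.01, 0.01, 0.2, 0.01, 0.01],
        }
    )
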