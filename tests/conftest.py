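import numpy as np
import pandas as pd
import pytest

from nelfyap.dataio import CountMatrix


@pytest.fixture
def tiny_matrix() -> CountMatrix:
    """3 genes x 12 samples (4 conditions x 3 replicates), fixed values."""
    rng = np.random.default_rng(42)
    conditions = ["siControl", "siNELFA", "siYAP", "siNELFA_siYAP"]
    cols, rows = [], []
    for cond in conditions:
        for r in (1, 2, 3):
            cols.append(f"{cond}_r{r}")
            rows.append({"sample_id": f"{cond}_r{r}", "condition": cond, "replicate": r})
    counts = pd.DataFrame(
        rng.integers(10, 500, size=(3, 12)), index=["gA", "gB", "gC"], columns=cols
    )
    samples = pd.DataFrame(rows).set_index("sample_id")
    return CountMatrix(counts=counts, samples=samples)
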