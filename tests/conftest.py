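import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("ci")

from nmatransit.dataset import TransitivityDataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240612)


def random_small_dataset(rng, n_max=8, c_max=5, missing_rate=0.15):
    """Random tiny mixed-type dataset with injected missingness."""
    n = int(rng.integers(3, n_max + 1))
    n_chars = int(rng.integers(1, c_max + 1))
    labels = ["A vs B", "A vs C", "B vs C"]
    comparisons = [labels[int(rng.integers(0, 3))] for _ in range(n)]
    df = pd.DataFrame(
        {"study_id": [f"s{i}" for i in range(n)], "comparison": comparisons}
    )
    type_map = {}
    for c in range(n_chars):
        name = f"c{c}"
        kind = ["numeric", "binary", "categorical"][int(rng.integers(0, 3))]
        type_map[name] = kind
        if kind == "numeric":
            col = rng.normal(size=n).round(3).astype(object)
        elif kind == "binary":
            col = np.array(["yes", "no"])[rng.integers(0, 2, size=n)].astype(object)
        else:
            col = np.array(["u", "v", "w"])[rng.integers(0, 3, size=n)].astype(object)
        mask = rng.random(n) < missing_rate
        if mask.all():
            mask[int(rng.integers(0, n))] = False
        col[mask] = np.nan
        df[name] = col
    return TransitivityDataset.from_dataframe(df, type_map=type_map)
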