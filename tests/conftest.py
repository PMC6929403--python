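import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from cernet.matrix import ExpressionMatrix

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


def make_matrix(values, rna_types, n_pairs=None):
    """Build an ExpressionMatrix from a dict rna_id -> list of values, with
    the first half of the columns tumor and the second half paired normals."""
    values = pd.DataFrame(values).T
    n = values.shape[1]
    assert n % 2 == 0
    half = n // 2
    pairs = [f"P{i}" for i in range(half)]
    samples = [f"P{i}-T" for i in range(half)] + [f"P{i}-N" for i in range(half)]
    values.columns = samples
    values.index.name = "rna_id"
    return ExpressionMatrix(
        values=values.astype(float),
        rna_types=pd.Series(rna_types),
        conditions=pd.Series(["tumor"] * half + ["normal"] * half, index=samples),
        pair_ids=pd.Series(pairs + pairs, index=samples),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix():
    """3 RNAs (one of each type) x 4 samples (2 tumor/normal pairs)."""
    return make_matrix(
        {
            "lnc1": [10.0, 20.0, 1.0, 2.0],
            "mir1": [1.0, 2.0, 10.0, 20.0],
            "mr1": [30.0, 40.0, 3.0, 4.0],
        },
        {"lnc1": "lncRNA", "mir1": "miRNA", "mr1": "mRNA"},
    )


@pytest.fixture
def random_matrix(rng):
    """50 RNAs x 12 samples (6 pairs) with some zeros sprinkled in."""
    n_rna, half = 50, 6
    vals = rng.gamma(2.0, 50.0, size=(n_rna, 2 * half))
    vals[rng.random(vals.shape) < 0.3] = 0.0
    ids = [f"R{i:02d}" for i in range(n_rna)]
    types = {rid: ["lncRNA", "miRNA", "mRNA"][i % 3] for i, rid in enumerate(ids)}
    return make_matrix({rid: vals[i] for i, rid in enumerate(ids)}, types)
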