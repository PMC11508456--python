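import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from proteomark import AbundanceMatrix

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


def make_matrix(values, case_ids, control_ids, accessions=None):
    """Small abundance matrix from an array and explicit group membership."""
    values = np.asarray(values, dtype=float)
    if accessions is None:
        accessions = [f"P{i:05d}" for i in range(1, values.shape[0] + 1)]
    samples = list(case_ids) + list(control_ids)
    groups = pd.Series(
        ["case"] * len(case_ids) + ["control"] * len(control_ids), index=samples
    )
    return AbundanceMatrix(pd.DataFrame(values, index=accessions, columns=samples), groups)


@pytest.fixture
def small_matrix():
    """5 proteins x 6 samples (3 case, 3 control) with assorted patterns."""
    rng = np.random.default_rng(42)
    vals = rng.lognormal(mean=5, sigma=1, size=(5, 6))
    vals[0, :3] = vals[0, 3:] * 2  # exact doubling of group means
    return make_matrix(vals, [f"c{i}" for i in range(3)], [f"h{i}" for i in range(3)])
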