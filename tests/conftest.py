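import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from pcphewas import CovariateSet, DosageMatrix, VariantRecord  # noqa: E402


def make_variant(vid="v1", maf=0.2, info=0.95, missing=0.0, pos=100):
    return VariantRecord(vid, "1", pos, "A", "G", maf, info, missing)


@pytest.fixture
def small_dosage_matrix():
    """4 samples x 3 variants, one missing entry."""
    rng = np.random.default_rng(7)
    dosages = rng.integers(0, 3, size=(4, 3)).astype(float)
    dosages[0, 1] = np.nan
    variants = [make_variant(f"v{i}", pos=100 + i) for i in range(1, 4)]
    return DosageMatrix([f"S{i}" for i in range(1, 5)], variants, dosages)


@pytest.fixture
def covariates():
    rng = np.random.default_rng(11)
    n = 300
    idx = pd.Index([f"S{i:06d}" for i in range(1, n + 1)], name="sample_id")
    return CovariateSet(pd.DataFrame(
        {"age": rng.normal(55, 8, n), "sex": rng.integers(0, 2, n).astype(float)},
        index=idx,
    ))
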