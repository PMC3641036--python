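import numpy as np
import pandas as pd
import pytest

from regenscreen.core_io import AnalysisConfig, ExpressionMatrix
from regenscreen.synthetic import SyntheticConfig, generate_dataset, toy_pipeline_b_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A modest seeded dataset shared by read-only tests."""
    return generate_dataset(SyntheticConfig(n_probes=800, rng_seed=11))


@pytest.fixture(scope="session")
def toy_dataset():
    return toy_pipeline_b_dataset()


@pytest.fixture()
def config():
    return AnalysisConfig(rng_seed=0)


@pytest.fixture()
def random_matrix():
    rng = np.random.default_rng(5)
    frame = pd.DataFrame(
        rng.uniform(1, 1000, (30, 8)),
        index=[f"p{i}" for i in range(30)],
        columns=[f"s{j}" for j in range(8)],
    )
    return ExpressionMatrix(frame, scale_tag="raw")
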