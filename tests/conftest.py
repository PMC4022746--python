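import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """A compact synthetic dataset: every sport cell scaled down but the
    sharing/reporting structure (cells below n=8) preserved."""
    from athleref import default_sim_config, load_table1, simulate_dataset

    cells = load_table1().copy()
    for col in ("n_common", "n_weight_height", "n_skinfold_circumference", "n_dxa"):
        cells[col] = np.minimum(cells[col], 12)
    return simulate_dataset(default_sim_config(seed=202, cells=cells))


@pytest.fixture(scope="session")
def small_frame(small_dataset):
    from athleref import derive_frame

    return derive_frame(small_dataset)
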