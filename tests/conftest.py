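import numpy as np
import pandas as pd
import pytest

from pollenifc import clustering, simulate


@pytest.fixture(scope="session")
def reference_panel() -> pd.DataFrame:
    return clustering.load_reference_panel()


@pytest.fixture(scope="session")
def sterility_values(reference_panel) -> np.ndarray:
    return reference_panel["sterility_mean"].to_numpy(dtype=float)


@pytest.fixture(scope="session")
def config80() -> simulate.GeneratorConfig:
    return simulate.default_config(80)


@pytest.fixture(scope="session")
def config120() -> simulate.GeneratorConfig:
    return simulate.default_config(120)


@pytest.fixture(scope="session")
def three_class_table(config120) -> pd.DataFrame:
    """A well-separated three-population event table with known truth."""
    rng = np.random.default_rng(424242)
    parts = []
    for label, n in (("viable", 10_000), ("dead", 6_000), ("sterile", 4_000)):
        parts.append(
            simulate.sample_population(
                config120.populations[label], n, rng, chip=config120.chip
            )
        )
    return pd.concat(parts, ignore_index=True)
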