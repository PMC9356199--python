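import numpy as np
import pandas as pd
import pytest

from ocoi import (
    MeasureDefinition,
    MeasureRegistry,
    SyntheticConfig,
    default_registry,
    generate_tract_frame,
)


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def toy_registry():
    """Two domains, three measures, one reverse-coded."""
    return MeasureRegistry(
        measures=(
            MeasureDefinition("m_a", "A", "housing", False, ("period_1", "period_2"), "percent"),
            MeasureDefinition("m_b", "B", "housing", True, ("period_2",), "index"),
            MeasureDefinition("m_c", "C", "environment", False, ("period_1", "period_2"), "rate"),
        ),
        version="toy",
    )


@pytest.fixture(scope="session")
def small_synthetic(registry):
    """A 200-tract synthetic table with defaults, shared across tests."""
    config = SyntheticConfig(n_tracts=200, seed=7)
    table, truth = generate_tract_frame(config, registry)
    return table, truth, config


def toy_table(values, fips=None, population=None):
    """Build a tract table from a measure->values mapping."""
    n = len(next(iter(values.values())))
    frame = pd.DataFrame(
        {
            "fips": fips if fips is not None else [f"99{i:09d}" for i in range(n)],
            "population": population if population is not None else np.full(n, 1000),
        }
    )
    for k, v in values.items():
        frame[k] = np.asarray(v, dtype=float)
    return frame
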