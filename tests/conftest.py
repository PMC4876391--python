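import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from elevbeta import (
    CommunityMatrix,
    PlotMetadata,
    SyntheticConfig,
    generate_assemblage,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def toy_matrix() -> CommunityMatrix:
    """Four plots in two bands, five species with clear band preferences."""
    counts = pd.DataFrame(
        {
            "sp_low_only": [5, 3, 0, 0],
            "sp_high_only": [0, 0, 4, 6],
            "sp_everywhere": [2, 2, 2, 2],
            "sp_one_plot": [0, 7, 0, 0],
            "sp_shared": [1, 0, 2, 1],
        },
        index=["p1", "p2", "p3", "p4"],
    )
    return CommunityMatrix(counts)


@pytest.fixture
def toy_metadata() -> PlotMetadata:
    return PlotMetadata(
        pd.DataFrame(
            {
                "plot_id": ["p1", "p2", "p3", "p4"],
                "transect": "T1",
                "band": ["800", "800", "1000", "1000"],
                "elevation_m": [805.0, 795.0, 1002.0, 998.0],
            }
        )
    )


@pytest.fixture(scope="session")
def small_transect():
    """A reduced synthetic transect (500 species) for fast integration tests."""
    cfg = SyntheticConfig(n_species=500, niche_width_sigma=150.0, seed=42)
    return generate_assemblage(cfg)
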