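import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from urbanfilter.landscape import Landscape
from urbanfilter.synth import SyntheticScenario, generate_dataset


@pytest.fixture
def toy_community() -> pd.DataFrame:
    """4 sites x 3 species with one very rare species and one poor site."""
    return pd.DataFrame(
        [[1, 0, 5], [0, 1, 4], [0, 0, 3], [2, 0, 0]],
        index=["s1", "s2", "s3", "s4"],
        columns=["spA", "spB", "spC"],
    )


@pytest.fixture
def two_square_landscape() -> Landscape:
    """Two unit-square patches with facing edges 10 m apart."""
    return Landscape({"a": box(0, 0, 1, 1), "b": box(11, 0, 12, 1)})


def null_scenario(seed: int, n_sites: int = 49, n_species: int = 50, **kw) -> SyntheticScenario:
    """Scenario with no planted trait-environment interaction."""
    return SyntheticScenario(n_sites=n_sites, n_species=n_species, seed=seed, **kw)


def planted_scenario(seed: int, coeff: float = 0.8, **kw) -> SyntheticScenario:
    """Scenario with a single urbanisation x polylectic interaction."""
    return SyntheticScenario(
        n_sites=49,
        n_species=50,
        seed=seed,
        interaction_coeffs={("urbanisation_pct", "diet:polylectic"): coeff},
        **kw,
    )


@pytest.fixture
def small_dataset():
    """A small synthetic dataset (no landscape geometry) for fast tests."""
    scen = SyntheticScenario(n_sites=20, n_species=40, seed=42)
    return generate_dataset(scen, with_landscape=False)
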