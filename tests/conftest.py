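"""Shared fixtures: the default synthetic experiment (expensive, built once
per session) and a miniature scene for fast plumbing tests."""

from __future__ import annotations

import numpy as np
import pytest

from fusionfield.pipeline import extract_features
from fusionfield.synthio import (SimConfig, YearSpec, default_treatments,
                                 simulate_experiment)


@pytest.fixture(scope="session")
def default_bundle():
    """The full default experiment: 6 treatments x 4 blocks x 2 years x 3
    harvests, 4 exclusions."""
    return simulate_experiment(SimConfig(seed=1))


@pytest.fixture(scope="session")
def feature_table(default_bundle):
    """Assembled feature table of the default scene (all 72 predictors)."""
    return extract_features(default_bundle)


def mini_config(seed: int = 5) -> SimConfig:
    """Two blocks, one year, two harvests, coarse grids: fast but complete."""
    return SimConfig(
        seed=seed, n_replicates=2,
        years=[YearSpec(1)],
        harvests_per_year=2,
        plot_length_m=6.0,
        point_density=400.0, ground_point_density=400.0,
        exclusions=[],
    )


@pytest.fixture(scope="session")
def mini_bundle():
    return simulate_experiment(mini_config())


@pytest.fixture(scope="session")
def mini_table(mini_bundle):
    return extract_features(mini_bundle)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
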