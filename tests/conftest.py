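"""Shared fixtures: small synthetic populations generated at test time."""

from datetime import date

import pytest

from partmig.config import SimConfig
from partmig import synthetic


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(n_residents=3, n_migrants=2, seed=42)


@pytest.fixture(scope="session")
def small_population(small_config):
    meta, truth = synthetic.generate_population(small_config)
    ambient = synthetic.generate_ambient_series(small_config)
    records = synthetic.generate_biologger_series(meta, truth, ambient, small_config)
    return small_config, meta, truth, ambient, records


@pytest.fixture(scope="session")
def winter_config() -> SimConfig:
    """Core-winter-only season: fast to generate, both strategies settled."""
    return SimConfig(
        n_residents=5,
        n_migrants=5,
        season_start=date(2016, 12, 1),
        season_end=date(2017, 1, 31),
        seed=7,
    )


@pytest.fixture(scope="session")
def winter_population(winter_config):
    meta, truth = synthetic.generate_population(winter_config)
    ambient = synthetic.generate_ambient_series(winter_config)
    records = synthetic.generate_biologger_series(meta, truth, ambient, winter_config)
    return winter_config, meta, truth, ambient, records
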