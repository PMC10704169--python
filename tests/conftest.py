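"""Shared fixtures: fragmentation rules, libraries, and the default
seven-strain synthetic study (generated once per session)."""

import pytest

from halolip.lipid_library import (
    LibraryConfig,
    build_default_library,
    enumerate_library,
    load_rules,
)
from halolip.synthetic_data import SimConfig, simulate


@pytest.fixture(scope="session")
def rules():
    return load_rules()


@pytest.fixture(scope="session")
def default_species():
    return enumerate_library(LibraryConfig())


@pytest.fixture(scope="session")
def default_library(rules):
    return build_default_library(LibraryConfig(), rules)


@pytest.fixture(scope="session")
def sim_default():
    """Default synthetic study at seed 42 (the study conditions)."""
    return simulate(config=SimConfig(seed=42))
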