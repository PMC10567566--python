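"""Shared fixtures: small seeded synthetic datasets."""

import warnings

import pandas as pd
import pytest

from perturbscope.synthetic_data import (
    CONTROL_LABEL,
    SimulationConfig,
    default_guide_library,
    simulate_screen,
)


@pytest.fixture(autouse=True)
def _quiet_simulation_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*pseudobulk column.*")
        warnings.filterwarnings("ignore", message=".*no nuclei drawn.*")
        warnings.filterwarnings("ignore", message=".*program is empty.*")
        yield


def small_config(**overrides) -> SimulationConfig:
    defaults = dict(
        n_genes=500,
        n_nuclei=1500,
        cell_types={"neuron": 1.0},
        guide_library=default_guide_library(
            n_targets=2, guides_per_target=1, n_controls=2
        ),
        program_size=30,
        effect_lfc=1.0,
        mosaic_fraction=0.5,
        zygosity_split=1.0,
        seed=42,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def screen_config() -> SimulationConfig:
    return small_config()


@pytest.fixture(scope="session")
def screen(screen_config):
    """A small single-cell-type screen: 2 targets, 2 SH guides, pi=0.5."""
    return simulate_screen(screen_config)


@pytest.fixture(scope="session")
def multi_ct_screen():
    """Two cell types, two targets, ambient guide noise."""
    cfg = small_config(
        n_nuclei=2000,
        cell_types={"neuron": 0.7, "glia": 0.3},
        ambient_rate=0.3,
        seed=11,
    )
    return cfg, simulate_screen(cfg)


@pytest.fixture(scope="session")
def control_label() -> str:
    return CONTROL_LABEL


@pytest.fixture()
def toy_guide_library():
    return pd.DataFrame(
        {
            "guide_id": ["gA", "gB", "gSH"],
            "target": ["GeneA", "GeneB", CONTROL_LABEL],
            "is_control": [False, False, True],
        }
    )
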