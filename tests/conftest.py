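"""Shared fixtures: a small synthetic study scored end to end."""

import pandas as pd
import pytest
from hypothesis import settings

from strainshare import snv_profiles as sp
from strainshare import transmission as tr
from strainshare.simulate import SimConfig, generate_study

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Scaled-down study: 6 goats + 6 pigs (3 of each cohoused), 2 timepoints."""
    return SimConfig(
        n_strains=12,
        n_goats=6,
        n_pigs=6,
        n_cohoused_goats=3,
        n_cohoused_pigs=3,
        timepoints=("3m", "12m"),
        n_positions_per_strain=80,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    metadata, abundance, coverage, pileup, truth = generate_study(small_config)
    return {
        "config": small_config,
        "metadata": metadata,
        "abundance": abundance,
        "coverage": coverage,
        "pileup": pileup,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def small_profiles(small_study) -> list[sp.StrainProfile]:
    return sp.build_profiles(small_study["pileup"], small_study["coverage"])


@pytest.fixture(scope="session")
def small_scores(small_study, small_profiles) -> pd.DataFrame:
    return tr.transmission_scores(small_profiles, small_study["metadata"])
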