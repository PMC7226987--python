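"""Shared fixtures: one moderately sized simulated study, generated once."""

from __future__ import annotations

import numpy as np
import pytest

from puregulon import SyntheticConfig, normalize_libraries
from puregulon import simulate as sim

STUDY_SEED = 11


@pytest.fixture(scope="session")
def study_config() -> SyntheticConfig:
    """The default study conditions at a size small enough for unit tests."""
    return SyntheticConfig(seed=STUDY_SEED, n_genes=800)


@pytest.fixture(scope="session")
def study(study_config):
    """(records, truth) for the shared simulated study."""
    return sim.generate_transcriptome(study_config)


@pytest.fixture(scope="session")
def study_records(study):
    return study[0]


@pytest.fixture(scope="session")
def study_truth(study):
    return study[1]


@pytest.fixture(scope="session")
def study_by_gene(study_records):
    return {r.gene: r for r in study_records}


@pytest.fixture(scope="session")
def rip_tables(study_config, study_truth):
    return sim.generate_rip_tables(study_config, study_truth)


@pytest.fixture(scope="session")
def kd_tables(study_config, study_truth):
    return sim.generate_kd_tables(study_config, study_truth)


@pytest.fixture(scope="session")
def normalized_tables(rip_tables, kd_tables):
    return {k: normalize_libraries(v) for k, v in {**rip_tables, **kd_tables}.items()}


@pytest.fixture()
def rng():
    return np.random.default_rng(STUDY_SEED)
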