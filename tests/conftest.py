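from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from foramdelim import synthdata as sd
from foramdelim.pipeline import run_pipeline
from foramdelim.readprep import PrimerSet


@pytest.fixture(scope="session")
def truth_taxonomy():
    return sd.generate_taxonomy(
        n_morphogroups=3, species_per_genus=2, types_per_species=2, seed=0
    )


@pytest.fixture(scope="session")
def references(truth_taxonomy):
    return sd.evolve_references(truth_taxonomy, seed=0)


@pytest.fixture(scope="session")
def outgroups():
    return sd.make_outgroup_references(seed=2)


@pytest.fixture(scope="session")
def small_dataset(truth_taxonomy, references, outgroups):
    """A 12-sample, 3600-read simulated survey used across test modules."""
    cfg = sd.SimulationConfig(n_stations=2, reads_per_sample=300, seed=1)
    return sd.simulate_reads(truth_taxonomy, references, cfg, outgroups=outgroups)


@pytest.fixture(scope="session")
def pipeline_result(small_dataset):
    return run_pipeline(small_dataset)


@pytest.fixture
def primers():
    return PrimerSet()
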