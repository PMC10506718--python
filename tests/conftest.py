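"""Shared fixtures: motif definitions, seed sets, and generated corpora.

The benchmark corpus and its pipeline run are session-scoped because the
full run is the expensive part of the suite; every test that needs the
default study conditions shares the same objects.
"""

import numpy as np
import pytest

from nemamp.amp_pipeline import PipelineConfig, run_pipeline
from nemamp.motif_engine import default_motifs
from nemamp.synthetic_data import SimConfig, default_seed_sets, generate_study


@pytest.fixture(scope="session")
def motifs():
    return default_motifs()


@pytest.fixture(scope="session")
def seed_sets():
    return default_seed_sets()


@pytest.fixture(scope="session")
def small_study():
    """A reduced corpus for fast pipeline-behaviour tests."""
    return generate_study(SimConfig(seed=11, n_genomes=2, n_decoys_per_genome=80))


@pytest.fixture(scope="session")
def default_study():
    """The benchmark corpus: 6 genomes x (500 decoys + 10 planted per group)."""
    return generate_study(SimConfig(seed=7))


@pytest.fixture(scope="session")
def default_result(default_study, seed_sets, motifs):
    """One full pipeline run on the benchmark corpus (shared; ~2 min)."""
    return run_pipeline(
        default_study.all_proteins(),
        seed_sets,
        motifs=motifs,
        domains=default_study.domains,
        config=PipelineConfig(seed=7),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
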