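import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import phylogerm as pg
from phylogerm import traits

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

warnings.filterwarnings("ignore", message="ArviZ")


@pytest.fixture(scope="session")
def study_sim():
    """One full synthetic study: 24 populations of 8 species, 768 plates."""
    cfg = pg.SimulationConfig(seed=3)
    records, truth = pg.simulate_germination(cfg)
    return cfg, records, truth


@pytest.fixture(scope="session")
def study_records(study_sim):
    return study_sim[1]


@pytest.fixture(scope="session")
def study_truth(study_sim):
    return study_sim[2]


@pytest.fixture(scope="session")
def study_tree(study_truth):
    return pg.parse_newick(study_truth.tree_newick)


@pytest.fixture(scope="session")
def study_A(study_tree):
    return pg.relatedness_matrix(study_tree)


@pytest.fixture(scope="session")
def study_cells(study_records):
    return traits.design_cells(study_records, "total", per_plate=False)


def make_plate(
    germ_strat=0,
    germ_incub=0,
    filled_ungerminated=0,
    n_sown=25,
    population="sp1_p1",
    species="sp1",
    sl=3,
    st=3.0,
    it="20/10",
    replicate=1,
):
    return traits.PlateRecord(
        species_code=species,
        population_id=population,
        strat_length_weeks=sl,
        strat_temp_c=st,
        incub_regime=it,
        replicate=replicate,
        n_sown=n_sown,
        germ_strat=germ_strat,
        germ_incub=germ_incub,
        filled_ungerminated=filled_ungerminated,
    )


@pytest.fixture
def plate_factory():
    return make_plate
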