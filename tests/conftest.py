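import numpy as np
import pytest

import mitomatch as mm
from mitomatch.mutation import MutationModel, RegionSpec


@pytest.fixture(scope="session")
def tiny_model():
    """A 20-site model (4 regions x 5 sites) with rates large enough that
    mutations are common on short genealogies."""
    # rates in table units (per site per 1e7 generations)
    return MutationModel(
        "tiny",
        (
            RegionSpec("HVS1+HVS2", 5, 2.0e5, 6.0e5),
            RegionSpec("PC1+PC2", 5, 0.5e5, 1.5e5),
            RegionSpec("PC3", 5, 1.0e5, 3.0e5),
            RegionSpec("rRNA+tRNA", 5, 0.5e5, 2.5e5),
        ),
    )


@pytest.fixture(scope="session")
def rieux():
    return mm.load_mutation_model("rieux")


@pytest.fixture(scope="session")
def oversti():
    return mm.load_mutation_model("oversti")


@pytest.fixture(scope="session")
def small_sim(tiny_model):
    """A small but structured simulation: 80 females x 30 generations with
    live-generation males, distinct synthetic founders, tiny genome."""
    scenario = mm.DemographyScenario(np.full(30, 80), label="small")
    genealogy = mm.simulate_genealogy(scenario, seed=101)
    pool = mm.synth_founders(
        40, genome_length=tiny_model, seed=102, sites_per_haplotype=(2, 6)
    )
    realization = mm.draw_rate_realization(tiny_model, seed=103)
    assignment = mm.assign_founders(pool, genealogy.n_females(0), seed=104)
    table, live = mm.drop_mutations(
        genealogy, tiny_model, realization, pool, assignment, seed=105
    )
    return {
        "scenario": scenario,
        "genealogy": genealogy,
        "pool": pool,
        "realization": realization,
        "assignment": assignment,
        "table": table,
        "live": live,
        "model": tiny_model,
    }
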