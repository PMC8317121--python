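import numpy as np
import pytest

from ribocompare.pipeline import (
    evaluate_pairs,
    inputs_from_simulation,
    select_paralog_pairs,
)
from ribocompare.profile_processing import DEFAULT_PARAMS, filter_domains
from ribocompare.ranking import build_pool
from ribocompare.synthetic_data import SimulationConfig, simulate_study
from ribocompare.usage_data import yeast_codon_usage


@pytest.fixture(scope="session")
def usage():
    return yeast_codon_usage()


@pytest.fixture(scope="session")
def small_study():
    """A small high-coverage study with strong paralog signal."""
    cfg = SimulationConfig(
        n_families=6, n_singletons=130, rho=0.9, depth=80.0, seed=42
    )
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def small_inputs(small_study):
    return inputs_from_simulation(small_study)


@pytest.fixture(scope="session")
def small_pool(small_inputs):
    retained, _ = filter_domains(small_inputs.domains, small_inputs.genes)
    pool, _ = build_pool(retained, small_inputs.genes)
    return pool


@pytest.fixture(scope="session")
def small_pairs(small_pool):
    pair_entries, _ = select_paralog_pairs(small_pool, identity_band=None)
    pairs, _ = evaluate_pairs(pair_entries, DEFAULT_PARAMS)
    assert pairs, "fixture study should yield processed pairs"
    return pairs
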