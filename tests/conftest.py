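"""Shared fixtures: small simulated genomes reused across test modules."""

from __future__ import annotations

import pytest

from ploidyscope.pipeline import run_scenario
from ploidyscope.simulate import build_genome, default_config


@pytest.fixture(scope="session")
def small_diploid_sim():
    return build_genome(default_config("diploid", seed=7, n_genes=24, n_scaffolds=2))


@pytest.fixture(scope="session")
def small_allo_sim():
    return build_genome(default_config("allopolyploid", seed=7, n_genes=30,
                                       n_scaffolds=2, outgroup_divergences=()))


@pytest.fixture(scope="session")
def small_allo_run():
    config = default_config("allopolyploid", seed=5, n_genes=40, n_scaffolds=2,
                            outgroup_divergences=())
    return run_scenario(config)
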