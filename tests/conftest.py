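import numpy as np
import pandas as pd
import pytest

import tetradiv as td


@pytest.fixture(scope="session")
def parent_pair():
    """Small diverged parent pair with repeats (deterministic)."""
    return td.simulate_parent_genomes(120_000, divergence=0.031, repeat_fraction=0.1, seed=42)


@pytest.fixture(scope="session")
def tetraploid(parent_pair):
    return td.make_tetraploid(parent_pair, n_scaffolds=4)


@pytest.fixture(scope="session")
def small_panel():
    """Three-species panel small enough for exhaustive checks."""
    # informative nucleotides scaled with the site counts so the per-site
    # heterozygosity targets stay attainable at this panel size
    specs = [
        td.PanelSpec("arabica", 60, 2.3e-4, selfing_generations=5, missing_rate=0.1,
                     n_sites=300, informative_nucleotides=60_000, rare_fraction=0.84),
        td.PanelSpec("canephora", 12, 2.6e-3, selfing_generations=0, missing_rate=0.1,
                     n_sites=400, informative_nucleotides=20_000),
        td.PanelSpec("eugenioides", 8, 1.1e-3, selfing_generations=0, missing_rate=0.1,
                     n_sites=300, informative_nucleotides=20_000),
    ]
    return td.simulate_species_panels(specs, homoeo_artifact_rate=0.05, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_complete_matrix(rng, n_individuals, n_sites):
    """Complete-data genotype matrix with at least one segregating site."""
    while True:
        codes = rng.integers(0, 3, size=(n_sites, n_individuals)).astype(np.int8)
        alt = codes.sum(axis=1)
        if ((alt > 0) & (alt < 2 * n_individuals)).any():
            break
    sites = pd.DataFrame(
        {"scaffold": "scf", "pos0": np.arange(n_sites), "ref": "A", "alt": "T"}
    )
    return td.GenotypeMatrix(
        individuals=[f"ind{i}" for i in range(n_individuals)],
        sites=sites,
        codes=codes,
        informative_nucleotides=max(n_sites, 100),
    )
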