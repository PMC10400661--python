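"""Shared fixtures: primer registry and small simulated communities."""

import numpy as np
import pytest

from amplikit import primer_model, read_sim


@pytest.fixture(scope="session")
def registry():
    return primer_model.load_registry()


@pytest.fixture(scope="session")
def v4(registry):
    return registry["V4"]


@pytest.fixture(scope="session")
def v12(registry):
    return registry["V1-V2"]


@pytest.fixture(scope="session")
def v12m(registry):
    return registry["V1-V2M"]


@pytest.fixture(scope="session")
def toy_refs_v12m(v12m):
    """Ten divergent references with exact V1-V2 loci (290 bp amplicons)."""
    return read_sim.make_toy_references(
        v12m, n_taxa=10, length=600, divergence=0.1, seed=5
    )


@pytest.fixture(scope="session")
def community_v12m(v12m, toy_refs_v12m):
    """A simulated 10-taxon library on the V1-V2M system (no host)."""
    abund = np.linspace(1, 3, 10)
    abund = abund / abund.sum()
    taxa = [
        read_sim.TaxonSpec(r[0], r[1], r[2], a)
        for r, a in zip(toy_refs_v12m, abund)
    ]
    config = read_sim.SimConfig(
        taxa=taxa, n_pairs=5000, error_rate=0.001, seed=13
    )
    reads1, reads2, truth = read_sim.simulate_library(v12m, config)
    return {
        "reads1": reads1,
        "reads2": reads2,
        "truth": truth,
        "abundances": abund,
        "taxa": taxa,
    }
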