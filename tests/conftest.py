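import numpy as np
import pytest

from rhodups.alignment import MultipleAlignment
from rhodups.simulate import (SimulationModel, compact_species_tree,
                              simulate_gene_family)
from rhodups.substmodel import GTRGamma


@pytest.fixture(scope="session")
def gtr_model():
    return GTRGamma(rates=(1.5, 4.0, 1.0, 1.2, 6.0, 1.0),
                    freqs=(0.22, 0.28, 0.24, 0.26), alpha=0.5, ncat=4)


@pytest.fixture(scope="session")
def b6_family(gtr_model):
    """Compact-tree gene family simulated under the B6 scenario."""
    truth, aln = simulate_gene_family(
        "B6", seed=11, species_tree=compact_species_tree(),
        sim_model=SimulationModel(site_count=1200))
    return truth, aln


def random_alignment(rng, taxa, n_sites):
    alphabet = list("ACGT")
    recs = [(t, "".join(rng.choice(alphabet, size=n_sites))) for t in taxa]
    return MultipleAlignment(recs)
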