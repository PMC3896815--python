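import logging

import numpy as np
import pytest

import netrepos as nr

logging.getLogger("netrepos").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def tiny_universe():
    return nr.GeneUniverse(genes=("a", "b", "c", "d", "e"))


@pytest.fixture(scope="session")
def small_world():
    """A small but fully featured synthetic world shared across tests."""
    return nr.generate(
        nr.WorldConfig(
            n_genes=300,
            n_drugs=10,
            n_diseases=3,
            n_planted_pairs=3,
            module_size=10,
            n_negatives=20,
            rng_seed=1,
        )
    )


@pytest.fixture(scope="session")
def default_world():
    """The full-scale default world (2343 genes); generated once per session."""
    return nr.generate(nr.WorldConfig(rng_seed=0))


def make_cooccurrence(universe, entity_ids, counts, abs_d=None, abs_g=None, n=None):
    counts = np.asarray(counts)
    if abs_d is None:
        abs_d = counts.sum(axis=1) + 100
    if abs_g is None:
        abs_g = counts.sum(axis=0) + 100
    if n is None:
        n = int(np.asarray(abs_d).sum() + np.asarray(abs_g).sum())
    return nr.CooccurrenceTable(
        entity_ids=tuple(entity_ids),
        universe=universe,
        abs_dg=counts,
        abs_d=abs_d,
        abs_g=abs_g,
        n=n,
    )
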