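import logging

import numpy as np
import pytest

from dungdna import TaxonNode, TaxonomyTable

logging.getLogger("dungdna").setLevel(logging.WARNING)


@pytest.fixture
def toy_taxonomy() -> TaxonomyTable:
    """10-node taxonomy: one order, two families, species spread so that
    every interesting LCA level is reachable."""
    nodes = {
        "root": TaxonNode("root", "root", None),
        "k": TaxonNode("Animalia", "kingdom", "root"),
        "ord": TaxonNode("Diptera", "order", "k"),
        "famA": TaxonNode("Muscidae", "family", "ord"),
        "famB": TaxonNode("Sepsidae", "family", "ord"),
        "genA": TaxonNode("Musca", "genus", "famA"),
        "genB": TaxonNode("Sepsis", "genus", "famB"),
        "spA1": TaxonNode("Musca autumnalis", "species", "genA"),
        "spA2": TaxonNode("Musca domestica", "species", "genA"),
        "spB1": TaxonNode("Sepsis cynipsea", "species", "genB"),
    }
    return TaxonomyTable(nodes)


def random_distance_matrix(n: int, rng: np.random.Generator) -> np.ndarray:
    """Random symmetric non-negative matrix with zero diagonal."""
    m = rng.uniform(0.05, 1.0, size=(n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return m
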