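import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from pathnet.annotations import CandidateGeneList, Pathway, PathwayCollection
from pathnet.gene_scores import GeneScoreTable


@pytest.fixture
def toy_collection():
    return PathwayCollection([
        Pathway("PW:A", "set A", "biological_process",
                frozenset({"g1", "g2", "g3"})),
        Pathway("PW:B", "set B", "molecular_function",
                frozenset({"g3", "g4"})),
        Pathway("PW:C", "set C", "cellular_component",
                frozenset({"g5"})),
    ])


@pytest.fixture
def toy_candidates():
    return CandidateGeneList([("g1", 50.0), ("g4", 45.0)])


@pytest.fixture
def uniform_table():
    rng = np.random.default_rng(42)
    genes = [f"g{i}" for i in range(500)]
    return GeneScoreTable("3h", genes, rng.uniform(size=500))
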