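import numpy as np
import pytest

from uniconsig import Concept, ConceptCompendium, generate_fixture


@pytest.fixture
def tiny_compendium() -> ConceptCompendium:
    return ConceptCompendium(
        [
            Concept("C1", "pair", frozenset({"a", "b"})),
            Concept("C2", "triple", frozenset({"b", "c", "d"})),
            Concept("C3", "disjoint", frozenset({"e", "f"})),
        ]
    )


@pytest.fixture
def planted_fixture():
    """Small planted-signal universe shared by the pipeline tests."""
    return generate_fixture(
        n_genes=500,
        n_concepts=30,
        concept_size_range=(10, 40),
        n_pathways=20,
        planted=[(0, 2.0)],
        noise_sd=1.0,
        seed=42,
    )


def random_compendium(rng: np.random.Generator, n_genes=100, n_concepts=12,
                      size_range=(5, 20), prefix="R") -> ConceptCompendium:
    """Uniformly random concepts over a synthetic gene universe."""
    genes = np.array([f"g{i:03d}" for i in range(n_genes)])
    concepts = []
    for i in range(n_concepts):
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        members = rng.choice(n_genes, size=size, replace=False)
        concepts.append(Concept(f"{prefix}{i:03d}", "", frozenset(genes[members])))
    return ConceptCompendium(concepts)
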