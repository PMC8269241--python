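import pytest

from virmatch import community as comm
from virmatch import pipeline as pipe
from virmatch.taxonomy import TaxonomyTree


@pytest.fixture(scope="session")
def community1():
    """The default synthetic community at seed 1 (shared, read-only)."""
    return comm.generate_community(1)


@pytest.fixture(scope="session")
def pipeline_result(tmp_path_factory):
    """One full pipeline run over the default community at seed 1."""
    out = tmp_path_factory.mktemp("run")
    return pipe.run_all(out, seed=1)


@pytest.fixture(scope="session")
def small_tree():
    """Two phyla / four genera toy taxonomy used by LCA and consensus tests."""
    tree = TaxonomyTree()
    rows = [
        ("P1", "Proteobacteria", "Gammaproteobacteria", "Pseudomonadales",
         "Pseudomonadaceae", "Pseudomonas", "Pseudomonas fluorescens"),
        ("P2", "Proteobacteria", "Gammaproteobacteria", "Pseudomonadales",
         "Pseudomonadaceae", "Pseudomonas", "Pseudomonas putida"),
        ("A1", "Proteobacteria", "Betaproteobacteria", "Burkholderiales",
         "Comamonadaceae", "Acidovorax", "Acidovorax delafieldii"),
        ("S1", "Actinobacteria", "Actinomycetia", "Streptomycetales",
         "Streptomycetaceae", "Streptomyces", "Streptomyces coelicolor"),
        ("B1", "Firmicutes", "Bacilli", "Bacillales",
         "Bacillaceae", "Bacillus", "Bacillus subtilis"),
    ]
    ranks = ("phylum", "class", "order", "family", "genus", "species")
    for strain, *lineage in rows:
        tree.add_strain(strain, list(zip(ranks, lineage)))
    return tree
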