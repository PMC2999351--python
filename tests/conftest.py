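import pytest

from neuromine import fixtures


@pytest.fixture(scope="session")
def small_corpus():
    """50 synthetic documents with planted mentions and MeSH links."""
    return fixtures.make_corpus(n_docs=50, mention_rate=2.0, seed=11)


@pytest.fixture(scope="session")
def small_lexicon(small_corpus):
    return small_corpus.lexicon()


@pytest.fixture(scope="session")
def noisefree_atlas():
    """10 genes on a 1000-voxel grid, one gene planted at fold 10 on a
    structure holding 10% of voxels, no noise."""
    return fixtures.make_voxel_atlas(
        n_genes=10,
        grid_dims=(10, 10, 10),
        n_structures=10,
        planted=[("g00003", "S000", 10.0)],
        noise_sigma=0.0,
        seed=0,
    )
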