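import pytest

from mtlineage import (
    load_gene_map,
    load_mummy_haplotype,
    load_toy_tree,
    synthetic_reference,
)


@pytest.fixture(scope="session")
def reference():
    return synthetic_reference()


@pytest.fixture(scope="session")
def gene_map():
    return load_gene_map()


@pytest.fixture(scope="session")
def toy_tree():
    return load_toy_tree()


@pytest.fixture(scope="session")
def mummy():
    """(haplotype, flagged-private set) from the packaged table."""
    return load_mummy_haplotype()
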