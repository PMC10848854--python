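import pytest

from mitochar import GeneFeature, MitoAnnotation, GeneticCode
from mitochar.datasets import (load_reference_annotation,
                               load_reference_codon_counts,
                               load_reference_pcg_orders)


@pytest.fixture(scope="session")
def reference_annotation():
    """The 42-feature oyster mitogenome annotation table."""
    return load_reference_annotation()


@pytest.fixture(scope="session")
def reference_codon_counts():
    return load_reference_codon_counts()


@pytest.fixture(scope="session")
def reference_pcg_orders():
    return load_reference_pcg_orders()


@pytest.fixture(scope="session")
def invertebrate_code():
    return GeneticCode.from_ncbi_id(5)


@pytest.fixture
def toy_annotation():
    """A minimal consistent circular annotation: gene(1-12), gene(21-26),
    genome 30 bp -> gaps 8 and 4 (closure)."""
    return MitoAnnotation(
        genome_length=30,
        features=(
            GeneFeature("Cox1", "PCG", 1, 12, start_codon="ATG",
                        stop_codon="TAA", declared_size=12, declared_gap=8),
            GeneFeature("trnM", "tRNA", 21, 26, declared_size=6,
                        declared_gap=4),
        ))
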