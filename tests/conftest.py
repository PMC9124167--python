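import numpy as np
import pytest

from codonclust import synthetic_data as sd


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def paper_like():
    return sd.paper_like_components()


@pytest.fixture(scope="session")
def synthetic_genome(paper_like):
    """One mid-size paper-like genome shared by read-only tests."""
    return sd.generate_genome(paper_like, n_genes=600, genome_id="shared", seed=7)


@pytest.fixture
def write_fasta(tmp_path):
    def _write(text, name="genes.fna"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write
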