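import numpy as np
import pytest

from enhancerscan.genome_io import GenomicInterval, TagTrack


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_track():
    return TagTrack({"chr1": np.array([100, 150, 200, 500, 1500, 1500, 1501])})


def random_intervals(rng, n, chrom="chr1", max_start=100_000, max_len=500):
    out = []
    for _ in range(n):
        start = int(rng.integers(0, max_start))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, start, start + length))
    return out


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """A small synthetic dataset shared across tests (session-scoped)."""
    from enhancerscan.synthetic import SyntheticSpec, generate_dataset

    out = tmp_path_factory.mktemp("tiny_synthetic")
    spec = SyntheticSpec(
        n_chroms=1,
        chrom_length=1_500_000,
        n_genes=12,
        n_enhancers=20,
        n_promoter_ncrna=8,
        seed=7,
    )
    manifest, truth = generate_dataset(spec, out)
    return spec, out, manifest, truth
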