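import numpy as np
import pytest

from sagqc import synthetic_data as sd


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_genome():
    return sd.make_genome(sd.GenomeModel(name="g1", length=50_000,
                                         gc_content=0.45, seed=101))


def make_mixture(host_gc=0.30, contam_gc=0.70, host_kb=250, contam_kb=25,
                 contig_len=5000, seed=0):
    """Two-genome contig mixture with truth labels (near-constant contig size)."""
    host_g = sd.make_genome(sd.GenomeModel(
        name="host", length=host_kb * 1000, gc_content=host_gc, seed=seed))
    hasm, _ = sd.fragment_genome(host_g, f=1.0, contig_len_mean=contig_len,
                                 seed=seed + 1, sigma=0.1)
    con_g = sd.make_genome(sd.GenomeModel(
        name="contam", length=contam_kb * 1000, gc_content=contam_gc,
        seed=seed + 2))
    casm, _ = sd.fragment_genome(con_g, f=1.0, contig_len_mean=contig_len,
                                 seed=seed + 3, sigma=0.1, label="contaminant")
    return sd.mix_contamination(hasm, casm, seed=seed + 4)
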