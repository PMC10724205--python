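import pytest

from pol2topo.io_formats import CoverageTrack, GenomicInterval
from pol2topo import synthetic_data as sd


def uniform_track(chrom="chr1", start=0, end=20_000, value=1.0):
    return CoverageTrack([(GenomicInterval(chrom, start, end), value)])


@pytest.fixture(scope="session")
def small_genome():
    """A tiny deterministic genome shared by read-only tests."""
    return sd.generate_genome(
        sd.SyntheticGenomeConfig(
            n_chroms=2,
            chrom_length=2_000_000,
            n_genes=30,
            n_enhancer_peaks=60,
            fraction_cpg_promoters=0.5,
            seed=11,
        )
    )
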