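import numpy as np
import pytest
from hypothesis import settings

from txforge.core import GenomicInterval, TranscriptModel
from txforge.synthetic import SimulationConfig, simulate_annotation

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_transcript(
    tid="t1",
    gid="g1",
    exons=((0, 100), (200, 300)),
    chrom="chr1",
    strand="+",
    tissues=(),
    **kw,
):
    return TranscriptModel(
        transcript_id=tid,
        gene_id=gid,
        exons=tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons),
        source_tissues=frozenset(tissues),
        **kw,
    )


@pytest.fixture(scope="session")
def sim():
    """One shared synthetic study: genes, genome and truth."""
    cfg = SimulationConfig(n_genes=60, seed=3)
    genes, genome, truth = simulate_annotation(cfg, seed=3)
    return cfg, genes, genome, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
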