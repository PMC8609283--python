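import pytest

from isokit.models import GenomicInterval, TranscriptModel
from isokit import synthetic_data as sd


def make_transcript(tid, strand, exons, chrom="chr1", gene_id="g1"):
    return TranscriptModel(
        tid,
        gene_id,
        chrom,
        strand,
        [GenomicInterval(chrom, s, e, strand) for s, e in exons],
    )


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic study: built once per session."""
    return sd.simulate(sd.SimulationConfig(seed=11))


@pytest.fixture()
def tm():
    return make_transcript
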