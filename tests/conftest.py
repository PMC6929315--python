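import numpy as np
import pytest

from retroscribe.config import PipelineConfig
from retroscribe.models import GenomicInterval, TranscriptModel


@pytest.fixture
def cfg() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_transcript(
    exons, tid="t1", gene="g1", chrom="chr1", strand="+", cds=None, source="reference"
) -> TranscriptModel:
    return TranscriptModel(
        tid,
        gene,
        chrom,
        strand,
        [GenomicInterval(chrom, s, e, strand) for s, e in exons],
        cds=cds,
        source=source,
    )


@pytest.fixture
def transcript_factory():
    return make_transcript
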