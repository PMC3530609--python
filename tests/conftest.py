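import numpy as np
import pytest

from retinomature.config import SimConfig


@pytest.fixture
def small_config():
    """A down-scaled study configuration for fast end-to-end tests."""
    return SimConfig(seed=11, n_genes=40, n_probesets=200, n_larvae=3,
                     settle_minutes=5, phase_minutes=2)


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


def make_transcript(tid, chrom="chr1", strand="+", exons=((100, 200),),
                    source="synthetic"):
    from retinomature.reannotate import TranscriptRecord
    return TranscriptRecord(transcript_id=tid, source_db=source, chrom=chrom,
                            strand=strand, cds_exons=tuple(exons))
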